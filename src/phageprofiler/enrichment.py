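"""Negative-binomial enrichment testing of selected vs unselected counts.

A self-contained NB Wald pipeline in the style of count-based
differential-expression tools: median-of-ratios size factors, per-peptide
method-of-moments dispersions shrunk toward an a/mu + b trend, a
two-group NB GLM with log link and size-factor offsets, a Wald test on
the condition coefficient, and Benjamini-Hochberg FDR.  Peptides are
called cleaved (enriched), depleted, or neutral at p_FDR < alpha.

The per-group log-mean MLE is computed by Newton iteration on the
profile score  dl/db = sum_j (y_j - mu_j)/(1 + alpha*mu_j)  with
mu_j = s_j * exp(b); the two group parameters are orthogonal, so the
Wald variance of the log fold change is 1/I_sel + 1/I_unsel with
expected information I = sum_j mu_j/(1 + alpha*mu_j).  No pseudocounts:
a group at zero runs to the coefficient floor and its standard error
grows accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .readproc import PeptideCountTable

LOG2 = np.log(2.0)
#: |log2 fold change| ceiling for groups running to zero (DESeq-style cap).
MAX_ABS_LOG2FC = 30.0

LABELS = ("cleaved", "depleted", "neutral")


@dataclass
class NBModelParams:
    size_factors: pd.Series
    dispersions: pd.Series
    trend_coefficients: tuple[float, float] | None = None  # (a, b) of a/mu + b


def filter_min_total(table: PeptideCountTable, min_total: int = 4) -> PeptideCountTable:
    """Keep peptides with >= min_total reads summed over all samples."""
    keep = table.counts.sum(axis=1) >= min_total
    return PeptideCountTable(counts=table.counts.loc[keep].copy(), roles=dict(table.roles))


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization.

    Per sample: median over all-positive peptides of count / geometric
    row mean.  Falls back to total-count ratios (scaled to geometric
    mean 1) when no peptide is positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        warnings.warn(
            "no peptide has positive counts in every sample; "
            "falling back to total-count normalization"
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    sub = arr[positive]
    log_ratios = np.log(sub) - np.mean(np.log(sub), axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _condition_columns(table: PeptideCountTable) -> tuple[list[str], list[str]]:
    sel = table.columns_for("selected")
    unsel = table.columns_for("unselected")
    if not sel or not unsel:
        raise ValueError("need at least one selected and one unselected sample")
    return sel, unsel


def estimate_dispersions(
    table: PeptideCountTable,
    size_factors: pd.Series,
    trend_weight: float = 0.5,
) -> NBModelParams:
    """Per-peptide NB dispersion: method of moments + trend shrinkage.

    Raw alpha_hat = max(0, (s^2 - mu)/mu^2) on size-factor-normalized
    counts, with the variance pooled within condition so the selection
    effect does not inflate it.  A mean-dispersion trend a/mu + b is fit
    by non-negative least squares over peptides with positive raw
    estimates, and the final dispersion is the trend_weight-blend of raw
    and trend values.
    """
    sel, unsel = _condition_columns(table)
    counts = table.counts
    norm = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()
    groups = [
        [counts.columns.get_loc(c) for c in cols] for cols in (sel, unsel)
    ]
    mu = norm.mean(axis=1)

    have_reps = all(len(g) >= 2 for g in groups)
    if have_reps:
        ss = np.zeros(len(counts))
        dof = 0
        for g in groups:
            sub = norm[:, g]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += len(g) - 1
        pooled_var = ss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mu > 0, (pooled_var - mu) / mu**2, 0.0)
        raw = np.clip(raw, 0.0, None)
    else:
        warnings.warn(
            "single replicate per condition: dispersion from the "
            "across-condition trend only (signal inflates it)"
        )
        var_all = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mu > 0, (var_all - mu) / mu**2, 0.0)
        raw = np.clip(raw, 0.0, None)

    # trend fit: alpha ~ a/mu + b, a,b >= 0
    use = (mu > 0) & (raw > 0)
    if use.sum() >= 10:
        X = np.column_stack([1.0 / mu[use], np.ones(use.sum())])
        coef, _ = nnls(X, raw[use])
        a, b = float(coef[0]), float(coef[1])
    else:
        a, b = 0.0, float(np.mean(raw)) if len(raw) else 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a / mu + b, b)

    if have_reps:
        final = trend_weight * trend + (1.0 - trend_weight) * raw
    else:
        final = trend
    final = np.clip(final, 1e-8, None)
    return NBModelParams(
        size_factors=size_factors,
        dispersions=pd.Series(final, index=counts.index, name="dispersion"),
        trend_coefficients=(a, b),
    )


def _group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray):
    """Vectorized Newton solve for per-peptide group log-mean with offsets.

    y: (n, m) counts, s: (m,) size factors, alpha: (n,) dispersions.
    Returns (b, info) where b is the log mean of the normalized count
    and info the expected Fisher information at the optimum.
    """
    n = y.shape[0]
    total = y.sum(axis=1)
    b = np.log(np.maximum(total / s.sum(), 1e-12))
    floor = -MAX_ABS_LOG2FC * LOG2
    b = np.clip(b, floor, None)
    a = alpha[:, None]
    for _ in range(60):
        mu = s[None, :] * np.exp(b)[:, None]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = np.clip(b + step, floor, MAX_ABS_LOG2FC * LOG2)
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s[None, :] * np.exp(b)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return b, info


def nb_wald_test(table: PeptideCountTable, params: NBModelParams) -> pd.DataFrame:
    """Two-group NB Wald test; returns base_mean, log2fc, se, p per peptide."""
    sel, unsel = _condition_columns(table)
    counts = table.counts
    sf = params.size_factors.reindex(counts.columns)
    alpha = params.dispersions.reindex(counts.index).to_numpy()

    norm = counts.to_numpy(dtype=float) / sf.to_numpy()
    base_mean = norm.mean(axis=1)

    y_sel = counts[sel].to_numpy(dtype=float)
    y_un = counts[unsel].to_numpy(dtype=float)
    b_sel, info_sel = _group_mle(y_sel, sf[sel].to_numpy(), alpha)
    b_un, info_un = _group_mle(y_un, sf[unsel].to_numpy(), alpha)

    log2fc = np.clip((b_sel - b_un) / LOG2, -MAX_ABS_LOG2FC, MAX_ABS_LOG2FC)
    with np.errstate(divide="ignore"):
        var = 1.0 / np.maximum(info_sel, 1e-300) + 1.0 / np.maximum(info_un, 1e-300)
    se = np.sqrt(var) / LOG2  # on the log2 scale
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "se": se, "p": p},
        index=counts.index,
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up with NaN propagation."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_peptides(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach p_fdr and cleaved/depleted/neutral labels to Wald results."""
    out = results.copy()
    out["p_fdr"] = adjust_bh(out["p"].to_numpy())
    label = np.full(len(out), "neutral", dtype=object)
    sig = out["p_fdr"].to_numpy() < alpha
    label[sig & (out["log2fc"].to_numpy() > 0)] = "cleaved"
    label[sig & (out["log2fc"].to_numpy() < 0)] = "depleted"
    out["label"] = label
    return out


def run_enrichment(
    table: PeptideCountTable,
    alpha: float = 0.05,
    min_total: int = 4,
    trend_weight: float = 0.5,
) -> pd.DataFrame:
    """Full stage: min-total filter -> size factors -> dispersions -> Wald -> BH.

    Returns a DataFrame indexed by peptide with columns base_mean,
    log2fc, se, p, p_fdr, label.
    """
    filtered = filter_min_total(table, min_total=min_total)
    if filtered.n_peptides == 0:
        return pd.DataFrame(
            columns=["base_mean", "log2fc", "se", "p", "p_fdr", "label"]
        )
    sf = estimate_size_factors(filtered.counts)
    params = estimate_dispersions(filtered, sf, trend_weight=trend_weight)
    results = nb_wald_test(filtered, params)
    return classify_peptides(results, alpha=alpha)
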