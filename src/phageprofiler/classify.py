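"""Forward-stepwise logistic regression over residue-presence features.

Cleaved peptides are trained against a size-matched random draw of
neutral (neither cleaved nor depleted) peptides.  Features are binary
indicators: global mode ``"X"`` marks residue X anywhere in the
hexapeptide; positional mode ``"X@k"`` marks residue X at position k.
At each step the candidate maximizing in-sample AUROC joins the model;
selection stops when the improvement falls below a tolerance.  A small
ridge penalty keeps coefficients finite under perfect separation.

Candidate fits use an in-package batched Newton (IRLS) solver so that a
whole step's candidate models are evaluated in one vectorized pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .nnk import AMINO_ACIDS, AA_INDEX, seq_to_array

DEFAULT_RIDGE = 1e-4


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # peptides x features, {0,1}
    y: np.ndarray  # 1 = cleaved, 0 = negative
    mode: str
    dropped: list[str] = field(default_factory=list)


@dataclass
class StepwiseResult:
    features: list[str]
    signs: list[str]  # '+' / '-'
    auroc_path: list[float]
    coefficients: pd.Series
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "sign": self.signs,
                "auroc_after_step": self.auroc_path,
                "coefficient": [self.coefficients[f] for f in self.features],
            }
        )


def build_features(
    positives, negatives, mode: str = "global"
) -> FeatureMatrix:
    """Binary residue-presence indicators for the two peptide pools."""
    if mode not in ("global", "positional"):
        raise ValueError(f"unknown mode {mode!r}")
    peptides = list(positives) + list(negatives)
    if not peptides:
        raise ValueError("empty input")
    y = np.concatenate(
        [np.ones(len(list(positives)), dtype=int), np.zeros(len(list(negatives)), dtype=int)]
    )
    arr = seq_to_array(peptides)
    codes = np.full(256, -1, dtype=np.int16)
    for aa, i in AA_INDEX.items():
        codes[ord(aa)] = i
    idx = codes[arr]
    if (idx < 0).any():
        raise ValueError("non-standard residue in peptides")
    n, length = idx.shape
    if mode == "global":
        X = np.zeros((n, 20), dtype=np.int8)
        for j in range(length):
            X[np.arange(n), idx[:, j]] = 1
        names = list(AMINO_ACIDS)
    else:
        X = np.zeros((n, 20 * length), dtype=np.int8)
        for j in range(length):
            X[np.arange(n), j * 20 + idx[:, j]] = 1
        names = [f"{aa}@{k + 1}" for k in range(length) for aa in AMINO_ACIDS]
        X = X.reshape(n, length, 20).transpose(0, 1, 2).reshape(n, -1)
    df = pd.DataFrame(X, columns=names)
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s)")
        df = df.drop(columns=constant)
    return FeatureMatrix(X=df, y=y, mode=mode, dropped=constant)


def sample_negatives(records: pd.DataFrame, n: int | None, rng) -> list[str]:
    """Uniform draw without replacement from neutral-labeled peptides."""
    pool = records.index[records["label"] == "neutral"].to_numpy()
    if n is None:
        n = int((records["label"] == "cleaved").sum())
    if len(pool) < n:
        raise ValueError(f"neutral pool ({len(pool)}) smaller than n ({n})")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return list(rng.choice(pool, size=n, replace=False))


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _fit_logistic_batch(
    X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE, n_iter: int = 30
) -> np.ndarray:
    """Ridge-penalized logistic MLE for a batch of design matrices.

    X: (C, n, p) stack of designs (including intercept column), y: (n,).
    Returns (C, p) coefficients.  Pure Newton/IRLS with a fixed ridge on
    non-intercept terms; the penalty bounds coefficients under perfect
    separation.
    """
    C, n, p = X.shape
    beta = np.zeros((C, p))
    pen = np.full(p, ridge)
    pen[0] = 0.0  # no penalty on the intercept
    eye = np.eye(p)
    for _ in range(n_iter):
        eta = np.einsum("cnp,cp->cn", X, beta)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-9, None)
        grad = np.einsum("cnp,cn->cp", X, (y[None, :] - mu)) - pen * beta
        hess = np.einsum("cnp,cn,cnq->cpq", X, w, X) + pen[None, :, None] * eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        step = np.clip(step, -10.0, 10.0)
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = DEFAULT_RIDGE):
    """Single ridge-logistic fit; X without intercept column.

    Returns (intercept, coefficients, scores).
    """
    design = np.column_stack([np.ones(len(y)), X])
    beta = _fit_logistic_batch(design[None, ...], np.asarray(y, float), ridge)[0]
    scores = design @ beta
    return float(beta[0]), beta[1:], scores


def cross_validated_auroc(
    features: FeatureMatrix,
    selected: list[str],
    k: int = 5,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Out-of-sample AUROC of a fixed feature set under k-fold CV.

    Off by default in the stepwise output (which reports in-sample
    AUROC); use this to gauge optimism of a selected model.
    """
    X = features.X[selected].to_numpy(dtype=float)
    y = features.y.astype(float)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError("k must be between 2 and the sample size")
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % k)
    scores = np.empty(n)
    for f in range(k):
        test = fold == f
        b0, coef, _ = fit_logistic(X[~test], y[~test], ridge=ridge)
        scores[test] = b0 + X[test] @ coef
    return auroc(scores, y)


def forward_stepwise(
    features: FeatureMatrix,
    tol: float = 0.001,
    max_features: int = 20,
    ridge: float = DEFAULT_RIDGE,
) -> StepwiseResult:
    """Greedy AUROC-maximizing forward selection of logistic features."""
    X_all = features.X.to_numpy(dtype=float)
    y = features.y.astype(float)
    names = list(features.X.columns)
    n = len(y)

    selected: list[int] = []
    signs: list[str] = []
    path: list[float] = []
    current_auc = 0.5
    remaining = list(range(len(names)))
    final_beta = np.array([np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))])

    while remaining and len(selected) < max_features:
        base = X_all[:, selected]  # (n, k)
        designs = np.empty((len(remaining), n, len(selected) + 2))
        designs[:, :, 0] = 1.0
        designs[:, :, 1 : len(selected) + 1] = base[None, :, :]
        designs[:, :, -1] = X_all[:, remaining].T
        betas = _fit_logistic_batch(designs, y, ridge)
        scores = np.einsum("cnp,cp->cn", designs, betas)
        aucs = np.array([auroc(s, y) for s in scores])
        best = int(np.argmax(aucs))
        if aucs[best] - current_auc < tol:
            break
        j = remaining[best]
        selected.append(j)
        remaining.remove(j)
        current_auc = float(aucs[best])
        path.append(current_auc)
        final_beta = betas[best]
        signs.append("+" if final_beta[-1] > 0 else "-")

    coef = pd.Series(
        final_beta[1:], index=[names[j] for j in selected], name="coefficient"
    )
    return StepwiseResult(
        features=[names[j] for j in selected],
        signs=signs,
        auroc_path=path,
        coefficients=coef,
        intercept=float(final_beta[0]),
    )
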