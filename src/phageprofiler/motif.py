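"""Substrate-motif construction from classified peptides.

Covers the anchored (Schechter-Berger) alignment of Arg-containing
peptides, position frequency matrices, differential (iceLogo-style)
logos with a two-proportion z significance and a three-state
enriched/depleted/unpopulated call, p-value-binned residue frequency
profiles, residue-proportion comparisons, and the NNK codon-count
expectations used to normalize observed frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nnk import AMINO_ACIDS, AA_INDEX, nnk_expected_frequencies, seq_to_array

__all__ = [
    "AlignedPeptideSet",
    "PositionFrequencyMatrix",
    "DifferentialLogo",
    "align_on_anchor",
    "position_frequencies",
    "differential_logo",
    "nnk_expected_frequencies",
    "pvalue_binned_profiles",
    "aa_proportion_comparison",
    "schechter_berger_label",
]


def schechter_berger_label(position: int, anchor: int) -> str:
    """Frame label of 1-based peptide position i given the P1 anchor k."""
    if position <= anchor:
        return f"P{anchor - position + 1}"
    return f"P{position - anchor}'"


def _frame_order(length: int = 6) -> list[str]:
    """All labels reachable for hexapeptides, N-terminal to C-terminal."""
    return [f"P{i}" for i in range(length, 0, -1)] + [
        f"P{i}'" for i in range(1, length)
    ]


@dataclass
class AlignedPeptideSet:
    """Peptides with a chosen P1 anchor each (1-based position of the anchor)."""

    peptides: list[str]
    anchors: np.ndarray
    anchor_residue: str
    skipped: int = 0

    def frame_labels(self, i: int) -> list[str]:
        """Frame labels of every residue of peptide i, N- to C-terminal."""
        k = int(self.anchors[i])
        return [
            schechter_berger_label(pos, k)
            for pos in range(1, len(self.peptides[i]) + 1)
        ]


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts/frequencies for a peptide pool.

    ``coverage`` is the per-position denominator (pool size for plain
    pools; the number of peptides whose frame reaches the label for
    aligned pools).
    """

    counts: pd.DataFrame  # positions x 20, integer counts
    pool_size: int
    coverage: pd.Series = None

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = pd.Series(self.pool_size, index=self.counts.index)

    @property
    def freq(self) -> pd.DataFrame:
        denom = self.coverage.replace(0, np.nan)
        return self.counts.div(denom, axis=0).fillna(0.0)

    def to_tsv(self, path) -> None:
        self.freq.rename_axis("position").to_csv(path, sep="\t")


def align_on_anchor(
    peptides,
    anchor_residue: str = "R",
    mode: str = "center_most",
) -> AlignedPeptideSet:
    """Assign each peptide's anchor residue to P1.

    ``single_only`` keeps only peptides with exactly one anchor residue;
    ``center_most`` picks, among multiple anchors, the position
    minimizing |pos - 3.5| with ties broken toward the lower position
    (so position 3 beats position 4).  Peptides without the anchor are
    skipped and tallied.
    """
    if mode not in ("single_only", "center_most"):
        raise ValueError(f"unknown mode {mode!r}")
    kept: list[str] = []
    anchors: list[int] = []
    skipped = 0
    for pep in peptides:
        positions = [i + 1 for i, aa in enumerate(pep) if aa == anchor_residue]
        if not positions:
            skipped += 1
            continue
        if mode == "single_only":
            if len(positions) != 1:
                skipped += 1
                continue
            anchor = positions[0]
        else:
            anchor = min(positions, key=lambda p: (abs(p - 3.5), p))
        kept.append(pep)
        anchors.append(anchor)
    if not kept:
        warnings.warn(f"no peptide contains anchor residue {anchor_residue!r}")
    return AlignedPeptideSet(
        peptides=kept,
        anchors=np.array(anchors, dtype=int),
        anchor_residue=anchor_residue,
        skipped=skipped,
    )


def _residue_codes(peptides: list[str]) -> np.ndarray:
    arr = seq_to_array(peptides)
    codes = np.full(256, -1, dtype=np.int16)
    for aa, i in AA_INDEX.items():
        codes[ord(aa)] = i
    out = codes[arr]
    if (out < 0).any():
        raise ValueError("non-standard residue in peptide pool")
    return out


def position_frequencies(pool) -> PositionFrequencyMatrix:
    """PFM for a plain pool (positions 1..6) or an AlignedPeptideSet (frames)."""
    if isinstance(pool, AlignedPeptideSet):
        return _aligned_frequencies(pool)
    peptides = list(pool)
    if not peptides:
        raise ValueError("empty peptide pool")
    codes = _residue_codes(peptides)
    n, length = codes.shape
    counts = np.zeros((length, 20), dtype=int)
    for j in range(length):
        counts[j] = np.bincount(codes[:, j], minlength=20)
    df = pd.DataFrame(
        counts, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )
    return PositionFrequencyMatrix(counts=df, pool_size=n)


def _aligned_frequencies(aligned: AlignedPeptideSet) -> PositionFrequencyMatrix:
    if not aligned.peptides:
        raise ValueError("empty aligned set")
    codes = _residue_codes(aligned.peptides)
    n, length = codes.shape
    labels = _frame_order(length)
    label_index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), 20), dtype=int)
    coverage = np.zeros(len(labels), dtype=int)
    for i in range(n):
        k = int(aligned.anchors[i])
        for j in range(length):
            li = label_index[schechter_berger_label(j + 1, k)]
            counts[li, codes[i, j]] += 1
            coverage[li] += 1
    present = coverage > 0
    df = pd.DataFrame(
        counts[present],
        index=pd.Index([l for l, p in zip(labels, present) if p], name="position"),
        columns=list(AMINO_ACIDS),
    )
    cov = pd.Series(coverage[present], index=df.index)
    return PositionFrequencyMatrix(counts=df, pool_size=n, coverage=cov)


@dataclass
class DifferentialLogo:
    """Per position/residue comparison of a cleaved pool vs an uncleaved pool."""

    freq_cleaved: pd.DataFrame
    freq_uncleaved: pd.DataFrame
    diff: pd.DataFrame
    ratio: pd.DataFrame
    z: pd.DataFrame
    call: pd.DataFrame  # 'enriched' | 'depleted' | 'unpopulated' | ''

    def to_tsv(self, path) -> None:
        long = pd.concat(
            {
                "freq_cleaved": self.freq_cleaved.stack(),
                "freq_uncleaved": self.freq_uncleaved.stack(),
                "diff": self.diff.stack(),
                "ratio": self.ratio.stack(),
                "z": self.z.stack(),
                "call": self.call.stack(),
            },
            axis=1,
        )
        long.index.names = ["position", "residue"]
        long.to_csv(path, sep="\t")


def differential_logo(
    cleaved: PositionFrequencyMatrix,
    uncleaved: PositionFrequencyMatrix,
    min_support: int = 5,
    z_alpha: float = 0.05,
) -> DifferentialLogo:
    """Two-proportion z comparison of per-position residue frequencies.

    z = d / sqrt(fbar(1-fbar)(1/n1+1/n2)) with pooled fbar; cells are
    called enriched/depleted when |z| exceeds the two-sided normal
    quantile at z_alpha, and unpopulated when counts fall below
    min_support in both pools (overriding any call).
    """
    if cleaved.pool_size == 0 or uncleaved.pool_size == 0:
        raise ValueError("zero-size pool")
    positions = cleaved.counts.index.intersection(uncleaved.counts.index)
    c1 = cleaved.counts.loc[positions]
    c2 = uncleaved.counts.loc[positions]
    n1 = cleaved.coverage.loc[positions].to_numpy()[:, None].astype(float)
    n2 = uncleaved.coverage.loc[positions].to_numpy()[:, None].astype(float)
    f1 = c1.to_numpy() / np.maximum(n1, 1)
    f2 = c2.to_numpy() / np.maximum(n2, 1)
    d = f1 - f2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f2 > 0, f1 / np.where(f2 > 0, f2, 1.0), np.where(f1 > 0, np.inf, np.nan))
        fbar = (c1.to_numpy() + c2.to_numpy()) / (n1 + n2)
        var = fbar * (1.0 - fbar) * (1.0 / n1 + 1.0 / n2)
        z = np.where(var > 0, d / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    crit = stats.norm.ppf(1.0 - z_alpha / 2.0)
    call = np.full(d.shape, "", dtype=object)
    call[z > crit] = "enriched"
    call[z < -crit] = "depleted"
    unpop = (c1.to_numpy() < min_support) & (c2.to_numpy() < min_support)
    call[unpop] = "unpopulated"

    def _df(a):
        return pd.DataFrame(a, index=positions, columns=list(AMINO_ACIDS))

    return DifferentialLogo(
        freq_cleaved=_df(f1),
        freq_uncleaved=_df(f2),
        diff=_df(d),
        ratio=_df(ratio),
        z=_df(z),
        call=_df(call),
    )


# --- residue-content summaries ---------------------------------------------


def _residue_proportions(peptides) -> pd.Series:
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty pool")
    codes = _residue_codes(peptides)
    counts = np.bincount(codes.ravel(), minlength=20)
    return pd.Series(counts / counts.sum(), index=list(AMINO_ACIDS))


def aa_proportion_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Relative residue proportions in cleaved, depleted, and all peptides.

    ``records`` is the classified enrichment table (peptides as index,
    ``label`` column).  Rows are sorted by the cleaved-minus-depleted
    difference, largest first.
    """
    pools = {
        "cleaved": records.index[records["label"] == "cleaved"],
        "depleted": records.index[records["label"] == "depleted"],
        "all": records.index,
    }
    out = {}
    for name, peptides in pools.items():
        if len(peptides) == 0:
            warnings.warn(f"empty {name} pool: proportions undefined")
            out[name] = pd.Series(np.nan, index=list(AMINO_ACIDS))
        else:
            out[name] = _residue_proportions(peptides)
    df = pd.DataFrame(out)
    df["difference"] = df["cleaved"] - df["depleted"]
    return df.sort_values("difference", ascending=False).rename_axis("residue")


def pvalue_binned_profiles(
    records: pd.DataFrame, min_bin: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean residue frequencies for peptides binned by p-value magnitude.

    Peptides are split into an enriched arm (log2fc > 0) and a depleted
    arm; each arm is cut into one-decade bins on log10(p_fdr) and
    adjacent bins are merged until every remaining bin holds more than
    ``min_bin`` peptides (an arm with too few peptides collapses to a
    single bin).  Rows are ordered from most significantly enriched to
    most significantly depleted.  Returns (profiles, bin_info).
    """
    profiles: list[pd.Series] = []
    info: list[dict] = []
    for arm, sign in (("enriched", 1), ("depleted", -1)):
        mask = records["log2fc"] > 0 if sign > 0 else records["log2fc"] <= 0
        sub = records.loc[mask]
        if len(sub) == 0:
            continue
        logp = np.log10(np.clip(sub["p_fdr"].to_numpy(dtype=float), 1e-300, 1.0))
        order = np.argsort(logp)  # most significant first
        logp_sorted = logp[order]
        peptides = sub.index.to_numpy()[order]
        bins = _decade_bins(logp_sorted, min_bin)
        if sign < 0:  # depleted arm runs least -> most significant
            bins = [b for b in reversed(bins)]
        for b in bins:
            pool = peptides[b]
            profiles.append(_residue_proportions(pool))
            info.append(
                {
                    "arm": arm,
                    "n_peptides": len(pool),
                    "mean_log10_p_fdr": float(np.mean(logp_sorted[b])),
                }
            )
    prof_df = pd.DataFrame(profiles).reset_index(drop=True)
    prof_df.index.name = "bin"
    info_df = pd.DataFrame(info)
    info_df.index.name = "bin"
    return prof_df, info_df


def _decade_bins(logp_sorted: np.ndarray, min_bin: int) -> list[np.ndarray]:
    """Cut ascending log10 p values into decade bins, merging small ones."""
    n = len(logp_sorted)
    idx = np.arange(n)
    if n <= min_bin:
        return [idx]
    decades = np.floor(logp_sorted).astype(int)
    groups: list[np.ndarray] = [
        idx[decades == d] for d in np.unique(decades)
    ]  # ascending decade = most significant first
    # merge any bin not exceeding min_bin into its neighbor
    changed = True
    while changed and len(groups) > 1:
        changed = False
        for i, g in enumerate(groups):
            if len(g) <= min_bin:
                j = i - 1 if i > 0 else i + 1
                groups[j] = np.concatenate([groups[min(i, j)], groups[max(i, j)]])
                del groups[i]
                changed = True
                break
    return groups


def plot_differential_heatmap(logo: DifferentialLogo, path) -> None:
    """Three-state heatmap (enriched green / depleted red / unpopulated black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    states = np.zeros(logo.call.shape)
    states[logo.call.to_numpy() == "enriched"] = 1
    states[logo.call.to_numpy() == "depleted"] = -1
    states[logo.call.to_numpy() == "unpopulated"] = -2
    cmap = ListedColormap(["black", "#c0392b", "white", "#27ae60"])
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(logo.call) + 1.5))
    ax.imshow(states, cmap=cmap, vmin=-2, vmax=1, aspect="auto")
    ax.set_xticks(range(20), list(AMINO_ACIDS))
    ax.set_yticks(range(len(logo.call.index)), logo.call.index)
    ax.set_xlabel("residue")
    ax.set_ylabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
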