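"""Synthetic substrate-phage experiments.

Generates NNK hexapeptide phage libraries, applies a single saturating
round of protease selection driven by a planted position-weight cleavage
motif, and emits paired-end FASTQ reads covering the 18-nt variable
region from both strands — so the whole downstream pipeline is testable
without touching real sequencing runs.

What is emulated: NNK codon composition, log-normal clone-abundance
skew, suppression of stop-codon clones (premature PIII termination
abolishes phage assembly, so displayed abundance of stop clones is
zero), per-base substitution errors with Phred qualities, and the
forward/reverse amplicon geometry with orientation seeds in the forward
flank.  Not emulated: phage amplification bias, PCR chimeras, indels.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .nnk import (
    AMINO_ACIDS,
    AA_INDEX,
    array_to_seqs,
    revcomp_array,
    seq_to_array,
    translate_array,
)

# Default amplicon layout.  The three 8-mer orientation seeds sit at
# offsets 0/8/16 of the forward flank; seeds are configuration, not
# biological constants.
DEFAULT_SEED_OFFSETS = (0, 8, 16)
DEFAULT_FORWARD_FLANK = "GCAGTCTGACCTGAACTCGCAAGGCA"  # 26 nt
DEFAULT_REVERSE_FLANK = "GGTGGAGGATCCGGAGGTTCAGCTGA"  # 26 nt


@dataclass
class NNKLibraryConfig:
    """Parameters of a simulated NNK phage display library.

    abundance_log_sd is the SD of the log-normal clone-abundance skew
    (dimensionless, default 1.0 — real libraries show per-clone counts
    spanning two orders of magnitude).  context_mode records whether the
    hexamer sits in a random-hexamer amplicon or in a fixed
    VWF73-style constant region; the flank texts carry the actual
    context either way.
    """

    n_clones: int
    abundance_log_sd: float = 1.0
    context_mode: str = "random_hexamer"
    forward_flank: str = DEFAULT_FORWARD_FLANK
    reverse_flank: str = DEFAULT_REVERSE_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        if self.abundance_log_sd < 0:
            raise ValueError("abundance_log_sd must be >= 0")
        if self.context_mode not in ("random_hexamer", "fixed_context"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        for flank in (self.forward_flank, self.reverse_flank):
            if set(flank) - set("ACGT"):
                raise ValueError("flanks must contain only A/C/G/T")


@dataclass
class NNKLibrary:
    """Ground-truth clone table: inserts, translations, display abundances.

    ``abundances`` are displayed (stop-free) abundances summing to 1;
    stop-containing clones are retained with abundance 0 so QC behaviour
    can be tested against the truth record.
    """

    config: NNKLibraryConfig
    inserts: list[str]
    peptides: list[str]
    abundances: np.ndarray
    has_stop: np.ndarray

    @property
    def n_clones(self) -> int:
        return len(self.inserts)

    def amplicons(self) -> np.ndarray:
        """(n_clones, L) ASCII matrix of full amplicons: flank + insert + flank."""
        fwd = seq_to_array([self.config.forward_flank] * max(self.n_clones, 1))
        rev = seq_to_array([self.config.reverse_flank] * max(self.n_clones, 1))
        if self.n_clones == 0:
            return np.empty((0, 0), dtype=np.uint8)
        ins = seq_to_array(self.inserts)
        return np.hstack([fwd, ins, rev])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "insert": self.inserts,
                "peptide": self.peptides,
                "abundance": self.abundances,
                "has_stop": self.has_stop,
            }
        )

    def to_tsv(self, path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CleavageMotifModel:
    """Position-weight ground truth for protease specificity.

    A hexapeptide's cleavage probability is
    ``logistic(intercept + sum_k weights[k, aa_k])`` with ``weights`` a
    6 x 20 table indexed by 1-based peptide position and residue.  A
    zero-weight model with intercept b cleaves every peptide with
    probability logistic(b).
    """

    weights: pd.DataFrame
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = self.weights.reindex(
            index=range(1, 7), columns=list(AMINO_ACIDS), fill_value=0.0
        ).astype(float)

    @classmethod
    def null(cls, intercept: float = 0.0) -> "CleavageMotifModel":
        w = pd.DataFrame(0.0, index=range(1, 7), columns=list(AMINO_ACIDS))
        return cls(weights=w, intercept=intercept)

    @classmethod
    def planted(
        cls,
        position: int = 4,
        residue: str = "R",
        weight: float = 4.0,
        intercept: float = -3.0,
    ) -> "CleavageMotifModel":
        """Single-anchor motif, e.g. the thrombin-like P1-Arg preference."""
        model = cls.null(intercept)
        model.weights.loc[position, residue] = weight
        return model

    def cleavage_probability(self, peptides) -> np.ndarray:
        """Vector of cleavage probabilities; stop-containing peptides get 0."""
        peptides = list(peptides)
        if not peptides:
            return np.empty(0)
        arr = seq_to_array(peptides)
        w = self.weights.to_numpy()
        aa_codes = np.full(256, -1, dtype=np.int16)
        for aa, i in AA_INDEX.items():
            aa_codes[ord(aa)] = i
        idx = aa_codes[arr]  # (n, 6); -1 marks stop/'*'
        valid = (idx >= 0).all(axis=1)
        score = np.zeros(len(peptides))
        safe = np.clip(idx, 0, 19)
        score = w[np.arange(6)[None, :], safe].sum(axis=1)
        prob = expit(score + self.intercept)
        prob[~valid] = 0.0
        return prob

    def to_tsv(self, path) -> None:
        out = self.weights.copy()
        out.insert(0, "position", out.index)
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{self.intercept}\n")
            out.to_csv(fh, sep="\t", index=False)


@dataclass
class SequencingConfig:
    """Paired-end run parameters (HiSeq-style 2x50 bp by default).

    per_base_error is the independent substitution probability per
    sequenced base; quality_mode 'independent' draws Phred scores
    regardless of whether the base is an error, 'error_aware' emits
    Q<5 at error sites so the quality filter has something to catch.
    """

    n_read_pairs: int
    read_length: int = 50
    per_base_error: float = 0.001
    quality_mode: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be in [0, 1]")
        if self.quality_mode not in ("independent", "error_aware"):
            raise ValueError(f"unknown quality_mode {self.quality_mode!r}")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")


def generate_nnk_inserts(n_inserts: int, n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """(n_inserts, 3*n_codons) ASCII matrix of NNK-random nucleotides."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    k_bases = np.frombuffer(b"GT", dtype=np.uint8)
    out = np.empty((n_inserts, 3 * n_codons), dtype=np.uint8)
    out[:, 0::3] = bases[rng.integers(0, 4, size=(n_inserts, n_codons))]
    out[:, 1::3] = bases[rng.integers(0, 4, size=(n_inserts, n_codons))]
    out[:, 2::3] = k_bases[rng.integers(0, 2, size=(n_inserts, n_codons))]
    return out


def generate_nnk_insert(n_codons: int, rng: np.random.Generator) -> str:
    """One NNK-random nucleotide text of 3*n_codons bases."""
    return array_to_seqs(generate_nnk_inserts(1, n_codons, rng))[0]


def build_library(config: NNKLibraryConfig) -> NNKLibrary:
    """Draw an NNK library with log-normal abundance skew.

    Stop-containing clones are flagged and carry zero displayed
    abundance (FUSE55-style display: a stop kills phage assembly), but
    stay in the record for QC oracles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clones
    if n == 0:
        return NNKLibrary(config, [], [], np.empty(0), np.empty(0, dtype=bool))
    ins_arr = generate_nnk_inserts(n, 6, rng)
    pep_arr = translate_array(ins_arr)
    has_stop = (pep_arr == ord("*")).any(axis=1)
    raw = np.exp(rng.normal(0.0, config.abundance_log_sd, size=n))
    raw[has_stop] = 0.0
    total = raw.sum()
    abundances = raw / total if total > 0 else raw
    return NNKLibrary(
        config=config,
        inserts=array_to_seqs(ins_arr),
        peptides=array_to_seqs(pep_arr),
        abundances=abundances,
        has_stop=has_stop,
    )


def apply_selection(library: NNKLibrary, motif: CleavageMotifModel) -> np.ndarray:
    """One saturating selection round: selected abundance ∝ input × P(cleave)."""
    if library.n_clones == 0:
        raise ValueError("cannot select from an empty library")
    prob = motif.cleavage_probability(library.peptides)
    sel = library.abundances * prob
    total = sel.sum()
    if total <= 0:
        raise ValueError("empty selection: all cleavage probabilities are zero")
    return sel / total


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _write_fastq(path, ids: list[bytes], seqs: np.ndarray, quals: np.ndarray) -> None:
    phred = (quals + 33).astype(np.uint8)
    seq_blob = seqs.tobytes()
    q_blob = phred.tobytes()
    n, length = seqs.shape
    buf = io.StringIO()
    for i in range(n):
        s = slice(i * length, (i + 1) * length)
        buf.write(f"@{ids[i].decode()}\n")
        buf.write(seq_blob[s].decode("ascii"))
        buf.write("\n+\n")
        buf.write(q_blob[s].decode("ascii"))
        buf.write("\n")
    with _open_out(path) as fh:
        fh.write(buf.getvalue())


def simulate_read_pairs(
    abundances: np.ndarray,
    library: NNKLibrary,
    cfg: SequencingConfig,
    r1_path,
    r2_path,
) -> np.ndarray:
    """Sample read pairs from clone abundances and write FASTQ mates.

    The forward read is the sense strand from amplicon position 0; the
    reverse read is the antisense strand from the amplicon 3' end.  Both
    must span the variable region, otherwise the configuration is
    rejected.  Returns the per-pair true clone indices (test oracle).
    """
    abundances = np.asarray(abundances, dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must be normalized")
    fwd_len = len(library.config.forward_flank)
    rev_len = len(library.config.reverse_flank)
    var_len = len(library.inserts[0]) if library.n_clones else 18
    amp_len = fwd_len + var_len + rev_len
    R = cfg.read_length
    if R < fwd_len + var_len or R < rev_len + var_len:
        raise ValueError(
            f"read_length {R} does not span the variable region "
            f"(need >= {max(fwd_len, rev_len) + var_len})"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_read_pairs
    clone_idx = rng.choice(library.n_clones, size=n, p=abundances)
    amps = library.amplicons()
    fwd = amps[clone_idx, :R].copy()
    rev = revcomp_array(amps[clone_idx, amp_len - R :])

    base_code = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_code[b] = i
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    quals = []
    for mate in (fwd, rev):
        err = rng.random(mate.shape) < cfg.per_base_error
        shift = rng.integers(1, 4, size=mate.shape, dtype=np.uint8)
        codes = base_code[mate]
        mate[err] = bases[(codes[err] + shift[err]) % 4]
        q = rng.integers(30, 41, size=mate.shape).astype(np.int16)
        if cfg.quality_mode == "error_aware":
            q[err] = rng.integers(0, 5, size=int(err.sum()))
        quals.append(q)

    ids = [f"sim:{i}".encode() for i in range(n)]
    _write_fastq(r1_path, ids, fwd, quals[0])
    _write_fastq(r2_path, ids, rev, quals[1])
    return clone_idx


@dataclass
class SimulatedSample:
    name: str
    role: str  # 'unselected' | 'selected'
    replicate: int
    r1: str
    r2: str
    clone_idx: np.ndarray = field(repr=False, default=None)


def simulate_experiment(
    library_cfg: NNKLibraryConfig,
    motif: CleavageMotifModel,
    seq_cfg: SequencingConfig,
    outdir,
    n_replicates: int = 2,
    gzip_out: bool = False,
) -> tuple[NNKLibrary, list[SimulatedSample]]:
    """Full experiment: one library, unselected + selected pools, replicates.

    Replicates are independent sequencing draws from the same pool
    (matching a library split across lanes).  seq_cfg.n_read_pairs is
    the per-sample pair count.  Writes per-sample mate files plus
    ground-truth TSVs under ``outdir``.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    library = build_library(library_cfg)
    selected = apply_selection(library, motif)
    library.to_tsv(os.path.join(outdir, "library_truth.tsv"))
    motif.to_tsv(os.path.join(outdir, "motif_truth.tsv"))
    prob = motif.cleavage_probability(library.peptides)
    pd.DataFrame(
        {"peptide": library.peptides, "cleavage_probability": prob}
    ).to_csv(os.path.join(outdir, "cleavage_truth.tsv"), sep="\t", index=False)

    ext = ".fastq.gz" if gzip_out else ".fastq"
    samples: list[SimulatedSample] = []
    for role, ab in (("unselected", library.abundances), ("selected", selected)):
        for rep in range(1, n_replicates + 1):
            name = f"{role}_{rep}"
            r1 = os.path.join(outdir, f"{name}_R1{ext}")
            r2 = os.path.join(outdir, f"{name}_R2{ext}")
            cfg_i = SequencingConfig(
                n_read_pairs=seq_cfg.n_read_pairs,
                read_length=seq_cfg.read_length,
                per_base_error=seq_cfg.per_base_error,
                quality_mode=seq_cfg.quality_mode,
                seed=seq_cfg.seed + 1000 * len(samples) + 7,
            )
            idx = simulate_read_pairs(ab, library, cfg_i, r1, r2)
            samples.append(SimulatedSample(name, role, rep, r1, r2, idx))
    return library, samples
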