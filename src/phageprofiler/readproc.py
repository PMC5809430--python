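"""Paired-end FASTQ -> quality-filtered peptide count table.

Three filters, applied to every read pair:

1. orientation — one mate must carry one of three 8-bp seed sequences
   at its stated offset in the forward-flank region (exact match; the
   redundancy of three seeds is what tolerates sequencing errors);
2. mate concordance — the sense and reverse-complemented antisense
   reads must match perfectly across the 18-nt variable region;
3. base quality — every variable-region base on both mates needs
   Phred >= 5 (of 40, +33 encoding).

Surviving regions are translated; stop-containing reads are tallied in
QC (with the stop codon identity) but excluded from the count table.
"""

from __future__ import annotations

import gzip
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nnk import (
    array_to_seqs,
    revcomp,
    revcomp_array,
    seq_to_array,
    translate,
    translate_array,
)

MIN_QUALITY = 5  # "a base pair quality score of at least 5 out of 40"

REASONS = ("no_seed", "mate_mismatch", "low_quality", "truncated")


@dataclass
class ExtractionTemplate:
    """Amplicon geometry: flanks, orientation seeds, variable region."""

    forward_flank: str
    reverse_flank: str
    seeds: tuple[tuple[int, str], ...]
    var_len: int = 18

    def __post_init__(self) -> None:
        if self.var_len % 3:
            raise ValueError("var_len must be divisible by 3")
        if len(self.seeds) == 0:
            raise ValueError("at least one orientation seed is required")
        for off, seed in self.seeds:
            if self.forward_flank[off : off + len(seed)] != seed:
                raise ValueError(
                    f"seed {seed!r} is not at offset {off} of the forward flank"
                )

    @property
    def var_start(self) -> int:
        return len(self.forward_flank)

    @property
    def amplicon_len(self) -> int:
        return len(self.forward_flank) + self.var_len + len(self.reverse_flank)

    @classmethod
    def from_library_config(cls, config, seed_offsets=(0, 8, 16), seed_len: int = 8):
        """Derive the template (seeds included) from a simulation config."""
        seeds = tuple(
            (off, config.forward_flank[off : off + seed_len]) for off in seed_offsets
        )
        return cls(
            forward_flank=config.forward_flank,
            reverse_flank=config.reverse_flank,
            seeds=seeds,
        )


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]


@dataclass
class SampleSpec:
    name: str
    r1: str
    r2: str
    role: str  # 'unselected' | 'selected'
    replicate: int = 1


@dataclass
class QCReport:
    """Per-sample filter accounting.

    ``passed_filter`` counts pairs surviving all three filters (this is
    Table-style "passed filter"; stop-containing passed reads are
    included here and broken out separately).
    """

    total_pairs: int = 0
    passed_filter: int = 0
    rejections: dict = field(default_factory=lambda: {r: 0 for r in REASONS})
    stop_read_count: int = 0
    stop_codon_breakdown: dict = field(
        default_factory=lambda: {"TAG": 0, "TAA": 0, "TGA": 0}
    )
    unique_peptides: int = 0

    @property
    def passed_fraction(self) -> float:
        return self.passed_filter / self.total_pairs if self.total_pairs else 0.0

    @property
    def stop_fraction(self) -> float:
        return self.stop_read_count / self.passed_filter if self.passed_filter else 0.0

    def to_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "passed_filter": self.passed_filter,
            "passed_fraction": self.passed_fraction,
            "rejections": dict(self.rejections),
            "stop_read_count": self.stop_read_count,
            "stop_fraction": self.stop_fraction,
            "stop_codon_breakdown": dict(self.stop_codon_breakdown),
            "unique_peptides": self.unique_peptides,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class PeptideCountTable:
    """Peptide x sample matrix of stop-free, filter-passing read counts."""

    counts: pd.DataFrame  # index: peptide, columns: sample names
    roles: dict  # sample name -> (role, replicate)

    def columns_for(self, role: str) -> list[str]:
        return [s for s, (r, _) in self.roles.items() if r == role]

    @property
    def n_peptides(self) -> int:
        return len(self.counts)

    def to_tsv(self, counts_path, design_path=None) -> None:
        self.counts.rename_axis("peptide").to_csv(counts_path, sep="\t")
        if design_path is not None:
            pd.DataFrame(
                [
                    {"sample": s, "role": r, "replicate": rep}
                    for s, (r, rep) in self.roles.items()
                ]
            ).to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "PeptideCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="peptide")
        design = pd.read_csv(design_path, sep="\t")
        roles = {
            row["sample"]: (row["role"], int(row["replicate"]))
            for _, row in design.iterrows()
        }
        return cls(counts=counts, roles=roles)


# --- per-pair reference path ----------------------------------------------


def orient_read_pair(pair: ReadPair, tmpl: ExtractionTemplate):
    """Exact-match any of the three seeds on either mate; sense mate first.

    Returns ``(oriented_pair, None)`` with mate 1 as the sense read, or
    ``(None, 'no_seed')``.
    """

    def has_seed(seq: str) -> bool:
        return any(seq[off : off + len(s)] == s for off, s in tmpl.seeds)

    if has_seed(pair.seq1):
        return pair, None
    if has_seed(pair.seq2):
        return (
            ReadPair(pair.id, pair.seq2, pair.seq1, pair.qual2, pair.qual1),
            None,
        )
    return None, "no_seed"


def extract_variable_region(pair: ReadPair, tmpl: ExtractionTemplate):
    """Mate-concordance + quality filters on an oriented pair.

    Returns ``(region, None)`` or ``(None, reason)`` with reason one of
    'truncated', 'mate_mismatch', 'low_quality'.
    """
    vs, vl = tmpl.var_start, tmpl.var_len
    if len(pair.seq1) < vs + vl:
        return None, "truncated"
    # The antisense mate reads from the amplicon 3' end; in its
    # reverse-complemented frame the variable region starts at
    # var_start - (amplicon_len - read_len).
    anti_start = vs - (tmpl.amplicon_len - len(pair.seq2))
    if anti_start < 0 or anti_start + vl > len(pair.seq2):
        return None, "truncated"
    sense_var = pair.seq1[vs : vs + vl]
    anti_rc = revcomp(pair.seq2)
    anti_var = anti_rc[anti_start : anti_start + vl]
    if sense_var != anti_var:
        return None, "mate_mismatch"
    q1 = pair.qual1[vs : vs + vl]
    q2 = pair.qual2[::-1][anti_start : anti_start + vl]
    if min(q1) < MIN_QUALITY or min(q2) < MIN_QUALITY:
        return None, "low_quality"
    return sense_var, None


def translate_nnk(region: str):
    """Translate a variable region; returns (peptide, stop_flag, stop_codon)."""
    peptide = translate(region)  # ValueError on non-ACGT / bad length
    if "*" in peptide:
        first = peptide.index("*")
        return peptide, True, region[3 * first : 3 * first + 3]
    return peptide, False, None


# --- FASTQ IO ---------------------------------------------------------------


def _open_in(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_pairs(r1_path, r2_path):
    """Yield ReadPair records from two mate FASTQ(.gz) files."""
    with _open_in(r1_path) as f1, _open_in(r2_path) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            h2 = f2.readline()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            yield ReadPair(
                id=h1.strip()[1:].split()[0],
                seq1=s1,
                seq2=s2,
                qual1=[ord(c) - 33 for c in q1],
                qual2=[ord(c) - 33 for c in q2],
            )


def _read_fastq_matrix(path):
    """Load a uniform-length FASTQ into (seq, qual) uint8 matrices, or None."""
    with _open_in(path) as fh:
        lines = fh.read().splitlines()
    n = len(lines) // 4
    if n == 0:
        return np.empty((0, 0), np.uint8), np.empty((0, 0), np.uint8)
    seqs = lines[1::4]
    quals = lines[3::4]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        return None
    seq_m = np.frombuffer("".join(seqs).encode("ascii"), np.uint8).reshape(n, length)
    q_m = (
        np.frombuffer("".join(quals).encode("ascii"), np.uint8).reshape(n, length)
        - 33
    )
    return seq_m, q_m


# --- bulk processing --------------------------------------------------------


def _process_matrices(seq1, q1, seq2, q2, tmpl: ExtractionTemplate):
    """Vectorized three-filter pass; returns (regions matrix, tallies dict)."""
    n = seq1.shape[0]
    tallies = {r: 0 for r in REASONS}
    if n == 0:
        return np.empty((0, tmpl.var_len), np.uint8), tallies

    def seed_hit(seq_m):
        hit = np.zeros(seq_m.shape[0], dtype=bool)
        for off, s in tmpl.seeds:
            if off + len(s) <= seq_m.shape[1]:
                s_arr = np.frombuffer(s.encode(), np.uint8)
                hit |= (seq_m[:, off : off + len(s)] == s_arr).all(axis=1)
        return hit

    hit1 = seed_hit(seq1)
    hit2 = seed_hit(seq2) & ~hit1
    oriented = hit1 | hit2
    tallies["no_seed"] = int((~oriented).sum())

    sense = np.where(hit2[:, None], seq2, seq1)
    anti = np.where(hit2[:, None], seq1, seq2)
    q_sense = np.where(hit2[:, None], q2, q1)
    q_anti = np.where(hit2[:, None], q1, q2)

    vs, vl = tmpl.var_start, tmpl.var_len
    anti_start = vs - (tmpl.amplicon_len - anti.shape[1])
    if sense.shape[1] < vs + vl or anti_start < 0 or anti_start + vl > anti.shape[1]:
        tallies["truncated"] = int(oriented.sum())
        return np.empty((0, vl), np.uint8), tallies

    sense_var = sense[:, vs : vs + vl]
    anti_var = revcomp_array(anti)[:, anti_start : anti_start + vl]
    match = (sense_var == anti_var).all(axis=1)
    tallies["mate_mismatch"] = int((oriented & ~match).sum())

    q_anti_var = q_anti[:, ::-1][:, anti_start : anti_start + vl]
    good_q = (q_sense[:, vs : vs + vl] >= MIN_QUALITY).all(axis=1) & (
        q_anti_var >= MIN_QUALITY
    ).all(axis=1)
    tallies["low_quality"] = int((oriented & match & ~good_q).sum())

    keep = oriented & match & good_q
    return sense_var[keep], tallies


def extract_passed_regions(r1_path, r2_path, tmpl: ExtractionTemplate) -> list[str]:
    """Variable regions of all pairs surviving the three filters (QC utility)."""
    m1 = _read_fastq_matrix(r1_path)
    m2 = _read_fastq_matrix(r2_path)
    if m1 is not None and m2 is not None:
        regions, _ = _process_matrices(m1[0], m1[1], m2[0], m2[1], tmpl)
        return array_to_seqs(regions)
    kept = []
    for pair in read_pairs(r1_path, r2_path):
        oriented, _ = orient_read_pair(pair, tmpl)
        if oriented is None:
            continue
        region, _ = extract_variable_region(oriented, tmpl)
        if region is not None:
            kept.append(region)
    return kept


def process_sample(r1_path, r2_path, tmpl: ExtractionTemplate):
    """Run the filters over one sample; returns (Counter of peptides, QCReport)."""
    qc = QCReport()
    m1 = _read_fastq_matrix(r1_path)
    m2 = _read_fastq_matrix(r2_path)
    if m1 is not None and m2 is not None:
        seq1, q1 = m1
        seq2, q2 = m2
        qc.total_pairs = seq1.shape[0]
        regions, tallies = _process_matrices(seq1, q1, seq2, q2, tmpl)
        qc.rejections.update(tallies)
    else:  # ragged read lengths: per-pair reference path
        kept = []
        for pair in read_pairs(r1_path, r2_path):
            qc.total_pairs += 1
            oriented, reason = orient_read_pair(pair, tmpl)
            if oriented is None:
                qc.rejections[reason] += 1
                continue
            region, reason = extract_variable_region(oriented, tmpl)
            if region is None:
                qc.rejections[reason] += 1
                continue
            kept.append(region)
        regions = seq_to_array(kept) if kept else np.empty((0, tmpl.var_len), np.uint8)

    qc.passed_filter = regions.shape[0]
    counter: Counter = Counter()
    if regions.shape[0]:
        uniq, inverse, counts = np.unique(
            regions, axis=0, return_inverse=True, return_counts=True
        )
        peps = array_to_seqs(translate_array(uniq))
        for region_row, pep, c in zip(uniq, peps, counts):
            if "*" in pep:
                qc.stop_read_count += int(c)
                region = array_to_seqs(region_row[None, :])[0]
                codon = region[3 * pep.index("*") : 3 * pep.index("*") + 3]
                if codon in qc.stop_codon_breakdown:
                    qc.stop_codon_breakdown[codon] += int(c)
            else:
                counter[pep] += int(c)
    qc.unique_peptides = len(counter)
    return counter, qc


def tally_peptides(
    samples: list[SampleSpec], tmpl: ExtractionTemplate
) -> tuple[PeptideCountTable, dict[str, QCReport]]:
    """Build the peptide x sample count table plus per-sample QC reports."""
    if not samples:
        raise ValueError("no samples given")
    counters: dict[str, Counter] = {}
    reports: dict[str, QCReport] = {}
    for spec in samples:
        counter, qc = process_sample(spec.r1, spec.r2, tmpl)
        if not counter:
            warnings.warn(f"sample {spec.name!r}: zero passed stop-free reads")
        counters[spec.name] = counter
        reports[spec.name] = qc
    all_peptides = sorted(set().union(*[c.keys() for c in counters.values()]))
    data = {
        name: [counters[name].get(p, 0) for p in all_peptides] for name in counters
    }
    counts = pd.DataFrame(data, index=pd.Index(all_peptides, name="peptide"), dtype=int)
    roles = {s.name: (s.role, s.replicate) for s in samples}
    return PeptideCountTable(counts=counts, roles=roles), reports
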