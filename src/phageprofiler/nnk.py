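"""NNK degenerate-codon bookkeeping and fast translation.

The NNK randomization scheme draws the first two bases of each codon
uniformly from {A,C,G,T} and the third from {G,T}.  This keeps all 20
amino acids reachable (31 sense codons) while leaving amber (TAG) as
the only stop codon in error-free NNK space: TAA and TGA both need an
A in the wobble position.

The genetic code is taken from Biopython's standard table; everything
here is derived from it by enumeration, never typed in by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
#: Canonical amino-acid ordering used for every 20-column table in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
STOP = "*"

#: All 64 codons mapped to single-letter amino acid, stops as '*'.
CODON_TO_AA = {
    a + b + c: standard_dna_table.forward_table.get(a + b + c, STOP)
    for a in BASES
    for b in BASES
    for c in BASES
}

#: The 32 codons reachable under NNK (third base G or T), lexicographic.
NNK_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in "GT")
NNK_STOP_CODONS = tuple(c for c in NNK_CODONS if CODON_TO_AA[c] == STOP)
NNK_SENSE_CODONS = tuple(c for c in NNK_CODONS if CODON_TO_AA[c] != STOP)

# --- fast byte-level translation ------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_AA_LUT = np.zeros(64, dtype=np.uint8)
for _a in BASES:
    for _b in BASES:
        for _c in BASES:
            _idx = 16 * _BASE_CODE[ord(_a)] + 4 * _BASE_CODE[ord(_b)] + _BASE_CODE[ord(_c)]
            _AA_LUT[_idx] = ord(CODON_TO_AA[_a + _b + _c])

_COMPLEMENT_CODE = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMPLEMENT_CODE[_x] = _y


def seq_to_array(seqs) -> np.ndarray:
    """Stack equal-length DNA/peptide strings into an (n, L) uint8 ASCII matrix."""
    if isinstance(seqs, str):
        seqs = [seqs]
    joined = "".join(seqs)
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    n = len(seqs)
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8)
    return arr.reshape(n, -1)


def array_to_seqs(arr: np.ndarray) -> list[str]:
    """Inverse of :func:`seq_to_array`."""
    if arr.size == 0:
        return []
    flat = arr.astype(np.uint8).tobytes().decode("ascii")
    n, length = arr.shape
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement each row of an ASCII nucleotide matrix."""
    return _COMPLEMENT_CODE[arr[:, ::-1]]


def revcomp(seq: str) -> str:
    return array_to_seqs(revcomp_array(seq_to_array([seq])))[0]


def translate_array(regions: np.ndarray) -> np.ndarray:
    """Translate an (n, 3k) ASCII nucleotide matrix into an (n, k) peptide matrix.

    Stops are emitted as ``*``.  Raises ``ValueError`` on non-ACGT input.
    """
    codes = _BASE_CODE[regions]
    if codes.size and codes.max() > 3:
        raise ValueError("non-ACGT character in nucleotide input")
    idx = 16 * codes[:, 0::3] + 4 * codes[:, 1::3] + codes[:, 2::3]
    return _AA_LUT[idx]


def translate(seq: str) -> str:
    """Translate one DNA string (length divisible by 3); stops become '*'."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return array_to_seqs(translate_array(seq_to_array([seq])))[0]


# --- NNK composition expectations -----------------------------------------


def nnk_codon_counts() -> dict[str, int]:
    """Number of NNK codons encoding each amino acid (enumerated, sums to 31)."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for codon in NNK_SENSE_CODONS:
        counts[CODON_TO_AA[codon]] += 1
    return counts


def nnk_expected_frequencies() -> tuple[pd.Series, float]:
    """Expected per-position residue frequencies under NNK randomization.

    Returns ``(freqs, stop_mass)`` where ``freqs`` is a Series over the 20
    amino acids (codon count / 32) and ``stop_mass`` is the remaining 1/32
    carried by the amber stop.
    """
    counts = nnk_codon_counts()
    freqs = pd.Series({aa: counts[aa] / 32.0 for aa in AMINO_ACIDS}, name="nnk_expected")
    stop_mass = len(NNK_STOP_CODONS) / 32.0
    return freqs, stop_mass


def expected_stop_fraction(n_codons: int = 6) -> float:
    """Probability that an n-codon NNK insert contains at least one stop.

    Computed by enumerating the 32 NNK codons against the genetic code
    (exactly one, TAG, is a stop), so 1 - (31/32)**n.
    """
    p_stop = len(NNK_STOP_CODONS) / len(NNK_CODONS)
    return 1.0 - (1.0 - p_stop) ** n_codons
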