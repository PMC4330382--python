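"""The 132-dimensional sequence+structure encoding of a protein-RNA pair.

A protein is represented by the normalized frequencies of (reduced
amino-acid group x protein-block letter) combinations: the 20 amino acids
collapse to 7 groups by dipole moment and side-chain volume, and crossing
those with the 16 protein-block letters gives 7 x 16 = 112 cells. An RNA is
represented by (nucleotide x secondary-structure element) frequencies:
4 x 5 = 20 cells. The pair vector is the concatenation, protein part first,
132 entries in total.

Index layout (fixed; any stable order is equivalent for the classifier but
must not drift across saved models):

* protein cell index = (group - 1) * 16 + rank of the PB letter in a..p
* RNA cell index = nucleotide rank (A,U,C,G) * 5 + class rank in S,H,L,B,I

Positions whose residue is unknown (X/N) or whose structure code is
unassigned (Z) are excluded from both the numerator and the denominator:
frequencies are normalized over observed combinations only.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np

from .structure_codes import PB_ALPHABET, RSS_ALPHABET, validate_pb_string, validate_rss_string

__all__ = [
    "AMINO_GROUPS",
    "N_PROTEIN_FEATURES",
    "N_RNA_FEATURES",
    "N_FEATURES",
    "FEATURE_NAMES",
    "layout_fingerprint",
    "reduce_protein_alphabet",
    "protein_feature_vector",
    "rna_feature_vector",
    "pair_feature_vector",
]

# 7-group reduced amino-acid alphabet (dipole moment / side-chain volume)
AMINO_GROUPS: dict[int, str] = {
    1: "AGV",
    2: "ILFP",
    3: "YMTS",
    4: "HNQW",
    5: "RK",
    6: "DE",
    7: "C",
}

_AA_TO_GROUP: dict[str, int] = {
    aa: g for g, members in AMINO_GROUPS.items() for aa in members
}

NUCLEOTIDES = "AUCG"

N_PROTEIN_FEATURES = len(AMINO_GROUPS) * len(PB_ALPHABET)
N_RNA_FEATURES = len(NUCLEOTIDES) * len(RSS_ALPHABET)
N_FEATURES = N_PROTEIN_FEATURES + N_RNA_FEATURES

assert N_PROTEIN_FEATURES == 112 and N_RNA_FEATURES == 20 and N_FEATURES == 132

FEATURE_NAMES: list[str] = [
    f"g{g}_{pb}" for g in AMINO_GROUPS for pb in PB_ALPHABET
] + [f"{nt}_{cls}" for nt in NUCLEOTIDES for cls in RSS_ALPHABET]


def layout_fingerprint() -> str:
    """Stable hash of the feature index order, embedded in saved models so a
    model never scores vectors laid out differently."""
    return hashlib.sha256(",".join(FEATURE_NAMES).encode()).hexdigest()[:16]


def reduce_protein_alphabet(seq: str) -> list[int]:
    """Per-residue group index 1-7; X maps to 0 (uncounted sentinel)."""
    out = []
    for i, aa in enumerate(seq.upper()):
        if aa == "X":
            out.append(0)
        elif aa in _AA_TO_GROUP:
            out.append(_AA_TO_GROUP[aa])
        else:
            raise ValueError(f"non-amino-acid character {aa!r} at position {i + 1}")
    return out


def protein_feature_vector(seq: str, pb: str) -> np.ndarray:
    """Normalized (group, PB-letter) co-occurrence frequencies, 112 entries.

    Zero vector when no position is countable (all X or all Z).
    """
    if len(seq) != len(pb):
        raise ValueError(f"sequence length {len(seq)} != PB string length {len(pb)}")
    validate_pb_string(pb)
    groups = reduce_protein_alphabet(seq)
    counts = np.zeros(N_PROTEIN_FEATURES)
    for g, code in zip(groups, pb):
        if g == 0 or code == "Z":
            continue
        counts[(g - 1) * len(PB_ALPHABET) + PB_ALPHABET.index(code)] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def rna_feature_vector(seq: str, rss: str) -> np.ndarray:
    """Normalized (nucleotide, RSS class) frequencies, 20 entries."""
    if len(seq) != len(rss):
        raise ValueError(f"sequence length {len(seq)} != RSS string length {len(rss)}")
    validate_rss_string(rss)
    seq = seq.upper()
    if "T" in seq:
        warnings.warn("T in RNA sequence transliterated to U")
        seq = seq.replace("T", "U")
    counts = np.zeros(N_RNA_FEATURES)
    for i, (nt, cls) in enumerate(zip(seq, rss)):
        if nt == "N":
            continue
        if nt not in NUCLEOTIDES:
            raise ValueError(f"non-nucleotide character {nt!r} at position {i + 1}")
        counts[NUCLEOTIDES.index(nt) * len(RSS_ALPHABET) + RSS_ALPHABET.index(cls)] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def pair_feature_vector(pvec: np.ndarray, rvec: np.ndarray) -> np.ndarray:
    """Concatenate protein (112) and RNA (20) parts into the 132-vector."""
    pvec = np.asarray(pvec, dtype=float)
    rvec = np.asarray(rvec, dtype=float)
    if pvec.shape != (N_PROTEIN_FEATURES,):
        raise ValueError(f"protein part must have {N_PROTEIN_FEATURES} entries")
    if rvec.shape != (N_RNA_FEATURES,):
        raise ValueError(f"RNA part must have {N_RNA_FEATURES} entries")
    return np.concatenate([pvec, rvec])


def encode_pair(protein_seq: str, pb: str, rna_seq: str, rss: str) -> np.ndarray:
    """Convenience: full 132-vector straight from sequences and codes."""
    return pair_feature_vector(
        protein_feature_vector(protein_seq, pb), rna_feature_vector(rna_seq, rss)
    )
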