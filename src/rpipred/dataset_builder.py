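"""Training-pair construction: contact labeling, redundancy removal, filters.

A (protein chain, RNA chain) pair from a solved complex is labelled
*positive* when at least one protein atom and one RNA atom lie within
3.40 Angstrom of each other — a distance covering strong/moderate hydrogen
bonds and energy-rich van der Waals contacts — and *negative* otherwise.
Homologous pairs (similar protein AND similar RNA, global-alignment identity
>= 30% on both sides) are collapsed to one representative; peptides
(< 25 aa) and small RNAs (< 15 nt) are excluded. For interaction lists
without experimental negatives, negatives are manufactured by keeping the
RNA column fixed and permuting the protein column so that no shuffled pair
coincides with a known positive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import PROTEIN, RNA, ChainRecord, ComplexRecord

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "LabeledPair",
    "DatasetConfig",
    "min_interchain_distance",
    "label_pair",
    "pairwise_identity",
    "remove_redundant_pairs",
    "apply_length_filters",
    "shuffle_negatives",
    "build_pairs_from_complex",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class DatasetConfig:
    """Thresholds of the dataset-construction procedure (defaults as used
    throughout: 3.40 A contact, 30% identity, 25 aa / 15 nt length floors)."""

    distance_threshold: float = 3.40
    identity_cutoff: float = 30.0
    min_protein_len: int = 25
    min_rna_len: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("distance_threshold", "identity_cutoff", "min_protein_len", "min_rna_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class LabeledPair:
    protein: ChainRecord
    rna: ChainRecord
    min_distance: float | None
    label: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protein.complex_id, self.protein.chain_id, self.rna.chain_id)


def min_interchain_distance(protein: ChainRecord, rna: ChainRecord) -> float:
    """Minimum Euclidean distance over all (protein atom, RNA atom) pairs, A.

    Every atom present in the record participates — hydrogens included when
    deposited. Residues without coordinates simply contribute no atoms.
    """
    a = protein.atom_coords()
    b = rna.atom_coords()
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError(
            f"undefined distance: chain {protein.chain_id if a.shape[0] == 0 else rna.chain_id}"
            " has no atoms"
        )
    return float(cdist(a, b).min())


def label_pair(min_distance: float, threshold: float = 3.40) -> str:
    """Positive iff the closest inter-chain atom pair is within threshold
    (boundary inclusive: exactly 3.40 A is a contact)."""
    if min_distance < 0:
        raise ValueError("distance must be non-negative")
    return POSITIVE if min_distance <= threshold else NEGATIVE


def _make_aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # EMBOSS-needle defaults: gap open 10, extend 0.5, end gaps free
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    if kind == PROTEIN:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.substitution_matrix = substitution_matrices.load("NUC.4.4")
    return aligner


_ALIGNERS: dict[str, Align.PairwiseAligner] = {}


def pairwise_identity(seq_a: str, seq_b: str, kind: str = PROTEIN) -> float:
    """Global-alignment percent identity (identical positions over alignment
    length x 100), EMBOSS-needle scoring."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 100.0
    if kind not in _ALIGNERS:
        _ALIGNERS[kind] = _make_aligner(kind)
    aligner = _ALIGNERS[kind]
    a = seq_a.replace("U", "T") if kind == RNA else seq_a
    b = seq_b.replace("U", "T") if kind == RNA else seq_b
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 100.0 * ident / len(s1)


def _redundant(p1: LabeledPair, p2: LabeledPair, cutoff: float) -> bool:
    return (
        pairwise_identity(p1.protein.sequence, p2.protein.sequence, PROTEIN) >= cutoff
        and pairwise_identity(p1.rna.sequence, p2.rna.sequence, RNA) >= cutoff
    )


def remove_redundant_pairs(
    pairs: list[LabeledPair], identity_cutoff: float = 30.0
) -> list[LabeledPair]:
    """Collapse homologous pairs (protein identity >= cutoff AND RNA identity
    >= cutoff) to one representative each.

    Redundancy classes are the connected components of the pairwise
    redundancy graph; the lexicographically smallest (complex id, protein
    chain, RNA chain) key represents each class, which reproduces the
    canonical four-chain worked example (A-Q, B-Q kept from
    {A-Q, B-Q, C-R, D-R} when A==C, B==D, Q==R).
    """
    if not pairs:
        raise ValueError("no pairs given")
    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if find(i) != find(j) and _redundant(pairs[i], pairs[j], identity_cutoff):
            parent[find(i)] = find(j)

    groups: dict[int, list[LabeledPair]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault(find(i), []).append(p)
    reps = [min(g, key=lambda p: p.key) for g in groups.values()]
    return sorted(reps, key=lambda p: p.key)


def apply_length_filters(
    pairs: list[LabeledPair], min_protein_len: int = 25, min_rna_len: int = 15
) -> list[LabeledPair]:
    """Drop peptide (< min_protein_len aa) and small-RNA (< min_rna_len nt)
    pairs."""
    return [
        p
        for p in pairs
        if len(p.protein) >= min_protein_len and len(p.rna) >= min_rna_len
    ]


def shuffle_negatives(
    positives: list[tuple[str, str]], seed: int, max_retries: int = 100
) -> list[tuple[str, str]]:
    """Generate negative pairs by permuting the protein column of a positive
    pair list, keeping the RNA column fixed.

    A seeded permutation is repaired by pairwise swaps until no generated
    pair coincides with a positive; if a pass makes no progress the whole
    permutation is redrawn (at most ``max_retries`` times). Deterministic
    given ``seed``; the multiset of proteins and the RNA column order are
    preserved exactly.
    """
    proteins = [p for p, _ in positives]
    n = len(proteins)
    if len(set(proteins)) < 2:
        raise ValueError("need at least two distinct proteins to shuffle")
    pos_set = set(positives)
    distinct = set(proteins)
    for prot, rna in positives:
        partners = {p for p, r in positives if r == rna}
        if distinct <= partners:
            raise ValueError(
                f"RNA {rna!r} is positive with every protein; "
                "no collision-free shuffle exists"
            )
    rnas = [r for _, r in positives]
    rng = np.random.default_rng(seed)
    col = [proteins[k] for k in rng.permutation(n)]
    for _ in range(max_retries):
        collisions = [i for i in range(n) if (col[i], rnas[i]) in pos_set]
        if not collisions:
            return list(zip(col, rnas))
        progress = False
        for i in collisions:
            if (col[i], rnas[i]) not in pos_set:
                continue  # already fixed by an earlier swap
            for j in rng.permutation(n):
                if j == i:
                    continue
                if (col[j], rnas[i]) not in pos_set and (col[i], rnas[j]) not in pos_set:
                    col[i], col[j] = col[j], col[i]
                    progress = True
                    break
        if not progress:
            col = [proteins[k] for k in rng.permutation(n)]
    raise ValueError(f"no collision-free permutation found in {max_retries} passes")


def build_pairs_from_complex(
    complex_record: ComplexRecord, config: DatasetConfig | None = None
) -> list[LabeledPair]:
    """All (protein, RNA) co-complex chain pairs with contact labels.

    Pairs whose distance is undefined (a chain without atoms) are excluded.
    """
    config = config or DatasetConfig()
    out: list[LabeledPair] = []
    for prot in complex_record.by_kind(PROTEIN):
        for rna in complex_record.by_kind(RNA):
            try:
                d = min_interchain_distance(prot, rna)
            except ValueError:
                continue
            out.append(LabeledPair(prot, rna, d, label_pair(d, config.distance_threshold)))
    return out
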