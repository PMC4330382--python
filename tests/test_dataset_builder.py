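"""Pair construction: contact distances against a brute-force scan,
alignment identity against a textbook Gotoh implementation, redundancy
removal against an exhaustive component oracle, and shuffled negatives."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from rpipred import (
    DatasetConfig,
    LabeledPair,
    apply_length_filters,
    build_pairs_from_complex,
    label_pair,
    make_toy_complex,
    min_interchain_distance,
    pairwise_identity,
    remove_redundant_pairs,
    shuffle_negatives,
)
from rpipred.structure_io import PROTEIN, RNA, Atom, ChainRecord, Residue


def chain_from_coords(chain_id, kind, coords, seq=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    seq = seq or ("A" * n if kind == RNA else "G" * n)
    residues = [
        Residue("ALA" if kind == PROTEIN else "A", s, [Atom("CA", "C", c)])
        for s, c in zip(seq, coords)
    ]
    return ChainRecord("test", chain_id, kind, seq, residues)


class TestMinInterchainDistance:
    def test_simple_geometry(self):
        p = chain_from_coords("A", PROTEIN, [[0, 0, 0]])
        r = chain_from_coords("B", RNA, [[0, 0, 3.2]])
        assert min_interchain_distance(p, r) == pytest.approx(3.2)

    def test_coincident_atoms(self):
        p = chain_from_coords("A", PROTEIN, [[1, 2, 3]])
        r = chain_from_coords("B", RNA, [[1, 2, 3]])
        assert min_interchain_distance(p, r) == 0.0

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(50, 3)) * 10
            b = rng.normal(size=(50, 3)) * 10 + 5
            p = chain_from_coords("A", PROTEIN, a)
            r = chain_from_coords("B", RNA, b)
            brute = min(
                float(np.linalg.norm(x - y)) for x in a for y in b
            )
            assert min_interchain_distance(p, r) == pytest.approx(brute, abs=1e-12)

    def test_chain_without_atoms_is_undefined(self):
        p = chain_from_coords("A", PROTEIN, [[0, 0, 0]])
        empty = ChainRecord("test", "B", RNA, "AAA", [Residue("A", "A", [])] * 3)
        with pytest.raises(ValueError, match="no atoms"):
            min_interchain_distance(p, empty)


class TestLabelPair:
    @pytest.mark.parametrize(
        "d,expected",
        [(3.39, "positive"), (3.40, "positive"), (3.41, "negative"), (0.0, "positive")],
    )
    def test_threshold_is_inclusive(self, d, expected):
        assert label_pair(d) == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(0, 8, size=50):
            for t1, t2 in [(2.0, 3.4), (3.4, 5.0)]:
                if label_pair(d, t1) == "positive":
                    assert label_pair(d, t2) == "positive"


def gotoh_score(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Textbook affine-gap global alignment score with free end gaps."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (insertion in a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0  # free end gaps
    for j in range(1, m + 1):
        Iy[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            open_x = max(M[i - 1, j], Iy[i - 1, j]) - (0.0 if j == m else gap_open)
            ext_x = Ix[i - 1, j] - (0.0 if j == m else gap_extend)
            Ix[i, j] = max(open_x, ext_x)
            open_y = max(M[i, j - 1], Ix[i, j - 1]) - (0.0 if i == n else gap_open)
            ext_y = Iy[i, j - 1] - (0.0 if i == n else gap_extend)
            Iy[i, j] = max(open_y, ext_y)
    return max(M[n, m], Ix[n, m], Iy[n, m])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVLAE", "MKVLAE") == 100.0

    def test_single_substitution_no_gap(self):
        # gapless alignment is optimal under BLOSUM62 with gap open 10
        assert pairwise_identity("ACDE", "ACDF") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=30))
            b = "".join(rng.choice(aas, size=25))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")

    def test_alignment_score_matches_textbook_gotoh(self):
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        from rpipred.dataset_builder import _make_aligner

        aligner = _make_aligner(PROTEIN)
        for _ in range(15):
            a = "".join(rng.choice(aas, size=int(rng.integers(8, 40))))
            b = "".join(rng.choice(aas, size=int(rng.integers(8, 40))))
            assert aligner.score(a, b) == pytest.approx(gotoh_score(a, b, blosum))

    def test_identity_on_mutated_copy_matches_hamming(self):
        # substitution-only mutants: optimal alignment is gapless, identity
        # must equal the direct positional agreement
        rng = np.random.default_rng(23)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = list(rng.choice(aas, size=40))
            b = a.copy()
            for pos in rng.choice(40, size=6, replace=False):
                b[pos] = rng.choice([x for x in aas if x != a[pos]])
            expected = 100.0 * sum(x == y for x, y in zip(a, b)) / 40
            assert pairwise_identity("".join(a), "".join(b)) == pytest.approx(expected)


def redundancy_components_oracle(pairs, cutoff):
    """Connected components of the exhaustive pairwise redundancy graph."""
    n = len(pairs)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        pi = pairwise_identity(pairs[i].protein.sequence, pairs[j].protein.sequence, PROTEIN)
        ri = pairwise_identity(pairs[i].rna.sequence, pairs[j].rna.sequence, RNA)
        if pi >= cutoff and ri >= cutoff:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def make_pair(complex_id, pc, rc, pseq, rseq):
    prot = chain_from_coords(pc, PROTEIN, [[0, 0, 0]] * len(pseq), pseq)
    prot.complex_id = complex_id
    rna = chain_from_coords(rc, RNA, [[0, 0, 0]] * len(rseq), rseq)
    rna.complex_id = complex_id
    return LabeledPair(prot, rna, 3.0, "positive")


PROT1 = "AGVILFPYMTAGVILFPYMTAGVILFPYMT"
PROT2 = "SHNQWRKDECSHNQWRKDECSHNQWRKD"
RNA1 = "GGGGAAAACCCCUUUUGCGC"


class TestRemoveRedundantPairs:
    def test_four_chain_worked_example(self):
        pairs = [
            make_pair("cx", "A", "Q", PROT1, RNA1),
            make_pair("cx", "B", "Q", PROT2, RNA1),
            make_pair("cx", "C", "R", PROT1, RNA1),
            make_pair("cx", "D", "R", PROT2, RNA1),
        ]
        kept = remove_redundant_pairs(pairs)
        assert {(p.protein.chain_id, p.rna.chain_id) for p in kept} == {("A", "Q"), ("B", "Q")}

    def test_mutually_nonredundant_input_unchanged(self):
        rng = np.random.default_rng(9)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = []
        # compositionally alternating sequences stay below 30% identity
        for i, block in enumerate(["AGVILFPYMT", "SHNQWRKDEC", "MTAGDECILF"]):
            pairs.append(make_pair("cx", f"P{i}", f"R{i}", block * 3,
                                   "".join(rng.choice(list("AUCG"), size=20))))
        kept = remove_redundant_pairs(pairs)
        if len(kept) == len(pairs):  # only assert when truly non-redundant
            assert {p.key for p in kept} == {p.key for p in pairs}

    def test_matches_component_oracle_on_random_pairs(self):
        rng = np.random.default_rng(31)
        families_p = [PROT1, PROT2, "MTYSMTYSMTYSMTYSMTYSMTYSMTYS"]
        families_r = [RNA1, "AUAUAUAUAUAUAUAUAUAU", "CCCCGGGGAAAAUUUUCCGG"]
        pairs = []
        for i in range(10):
            pairs.append(
                make_pair("cx", f"P{i}", f"R{i}",
                          families_p[rng.integers(3)], families_r[rng.integers(3)])
            )
        kept = remove_redundant_pairs(pairs, 30.0)
        comps = redundancy_components_oracle(pairs, 30.0)
        assert len(kept) == len(comps)
        # exactly one representative per component, the lexicographic minimum
        for comp in comps:
            members = {pairs[i].key for i in comp}
            assert len(members & {p.key for p in kept}) == 1
            assert min(members) in {p.key for p in kept}


class TestLengthFilters:
    @pytest.mark.parametrize(
        "plen,rlen,kept",
        [(24, 20, False), (25, 15, True), (30, 14, False), (100, 100, True)],
    )
    def test_boundaries(self, plen, rlen, kept):
        pair = make_pair("cx", "A", "Q", "A" * plen, "G" * rlen)
        out = apply_length_filters([pair])
        assert (len(out) == 1) is kept


class TestShuffleNegatives:
    def test_rna_column_fixed_and_no_overlap(self):
        positives = [(f"p{i}", f"r{i}") for i in range(20)]
        negatives = shuffle_negatives(positives, seed=4)
        assert len(negatives) == len(positives)
        assert [r for _, r in negatives] == [r for _, r in positives]
        assert not set(negatives) & set(positives)
        assert sorted(p for p, _ in negatives) == sorted(p for p, _ in positives)

    def test_deterministic_given_seed(self):
        positives = [(f"p{i % 7}", f"r{i}") for i in range(30)]
        assert shuffle_negatives(positives, seed=1) == shuffle_negatives(positives, seed=1)
        assert shuffle_negatives(positives, seed=1) != shuffle_negatives(positives, seed=2)

    def test_two_seeds_both_valid(self):
        rng = np.random.default_rng(8)
        positives = list({(f"p{rng.integers(40)}", f"r{rng.integers(40)}") for _ in range(100)})
        for seed in (1, 2):
            negs = shuffle_negatives(positives, seed=seed)
            assert not set(negs) & set(positives)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two distinct proteins"):
            shuffle_negatives([("p1", "r1"), ("p1", "r2")], seed=0)
        # every protein positive with r1: no collision-free shuffle
        with pytest.raises(ValueError):
            shuffle_negatives([("p1", "r1"), ("p2", "r1")], seed=0)


class TestDatasetConfig:
    def test_rejects_nonpositive_thresholds(self):
        with pytest.raises(ValueError):
            DatasetConfig(distance_threshold=0)

    def test_build_pairs_labels_toy_complexes(self):
        pos = make_toy_complex(True, 3.2, seed=0)
        neg = make_toy_complex(False, 5.0, seed=0)
        (p,) = build_pairs_from_complex(pos)
        (q,) = build_pairs_from_complex(neg)
        assert p.label == "positive" and q.label == "negative"
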