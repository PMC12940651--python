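"""Local-alignment similarity, reciprocal best hits, tandem/segmental calling."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import famscan as fs
from famscan.duplication import (
    DuplicationError,
    default_candidate_pairs,
    reciprocal_best_hits,
)
from famscan.genome_map import GeneModel, assign_ranks
from famscan.profiles import AA_ORDER, robinson_background

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(a: str, b: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Independent quadratic-space affine-gap local DP (gap of L costs open+ext*L)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            )
            best = max(best, M[i][j])
    return best


class DictSim:
    """Score stub for RBH logic tests (duck-typed SimilarityMatrix)."""

    def __init__(self, scores):
        self.scores = {frozenset(k): v for k, v in scores.items()}

    def score(self, a, b):
        return self.scores[frozenset((a, b))]


def random_proteins(rng, k, lo=20, hi=200):
    bg = robinson_background()
    return {
        f"p{i}": "".join(rng.choice(list(AA_ORDER), int(rng.integers(lo, hi + 1)), p=bg))
        for i in range(k)
    }


class TestSimilarity:
    def test_matches_textbook_pair_oracle(self):
        sim = fs.pairwise_similarity({"a": "HEAGAWGHEE", "b": "PAWHEAE"})
        assert sim.score("a", "b") == pytest.approx(gotoh_local("HEAGAWGHEE", "PAWHEAE"))

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(21)
        seqs = random_proteins(rng, 12, lo=20, hi=120)
        sim = fs.pairwise_similarity(seqs)
        ids = list(seqs)
        for a, b in zip(ids[::2], ids[1::2]):
            assert sim.score(a, b) == pytest.approx(gotoh_local(seqs[a], seqs[b]))

    def test_symmetry_and_self_score_dominance(self):
        rng = np.random.default_rng(22)
        seqs = random_proteins(rng, 6, lo=30, hi=80)
        sim = fs.pairwise_similarity(seqs)
        ids = list(seqs)
        for a in ids[:3]:
            for b in ids[3:]:
                assert sim.score(a, b) == sim.score(b, a)
                assert sim.score(a, a) >= sim.score(a, b)

    def test_identical_sequences_reach_self_score(self):
        sim = fs.pairwise_similarity({"a": "MKVLAW", "b": "MKVLAW"})
        assert sim.score("a", "b") == sim.score("a", "a")

    def test_empty_sequence_rejected(self):
        with pytest.raises(DuplicationError, match="empty"):
            fs.pairwise_similarity({"a": "", "b": "MK"})


class TestRBH:
    def test_mutual_best_pairs(self):
        sim = DictSim({("a1", "b1"): 9, ("a1", "b2"): 1, ("a2", "b1"): 1, ("a2", "b2"): 9})
        assert reciprocal_best_hits(sim, ["a1", "a2"], ["b1", "b2"]) == [
            ("a1", "b1"), ("a2", "b2"),
        ]

    def test_one_sided_best_excluded(self):
        # a1's best is b1, but b1's best is a2 -> (a1, b1) must not be paired
        sim = DictSim({("a1", "b1"): 5, ("a2", "b1"): 9, ("a1", "b2"): 1, ("a2", "b2"): 8})
        pairs = reciprocal_best_hits(sim, ["a1", "a2"], ["b1", "b2"])
        assert ("a1", "b1") not in pairs
        assert pairs == [("a2", "b1")]

    def test_all_equal_scores_tie_break_lexicographic(self):
        sim = DictSim({(a, b): 7 for a in ("a1", "a2") for b in ("b1", "b2")})
        pairs = reciprocal_best_hits(sim, ["a2", "a1"], ["b2", "b1"])
        assert pairs == [("a1", "b1")]  # deterministic, order-independent

    def test_matches_exhaustive_enumeration(self):
        """RBH equals the definition evaluated by brute force on <=10x10 matrices."""
        rng = np.random.default_rng(33)
        for _ in range(20):
            na, nb = int(rng.integers(1, 11)), int(rng.integers(1, 11))
            A = [f"a{i}" for i in range(na)]
            B = [f"b{j}" for j in range(nb)]
            scores = {(a, b): float(rng.integers(0, 12)) for a in A for b in B}
            sim = DictSim(scores)

            def best(q, pool, get):
                top = max(get(q, t) for t in pool)
                return min(t for t in pool if get(q, t) == top)

            expected = [
                (a, b)
                for a in A
                for b in [best(a, B, lambda q, t: scores[(q, t)])]
                if best(b, A, lambda q, t: scores[(t, q)]) == a
            ]
            assert reciprocal_best_hits(sim, A, B) == expected

    def test_partial_matching_no_repeats(self):
        rng = np.random.default_rng(34)
        seqs = random_proteins(rng, 8, lo=40, hi=80)
        sim = fs.pairwise_similarity(seqs)
        ids = sorted(seqs)
        pairs = reciprocal_best_hits(sim, ids[:4], ids[4:])
        used = [x for p in pairs for x in p]
        assert len(used) == len(set(used))

    def test_overlapping_sets_rejected(self):
        sim = DictSim({("a", "a"): 1})
        with pytest.raises(DuplicationError, match="disjoint"):
            reciprocal_best_hits(sim, ["a"], ["a"])


def adjacency_genome(family_positions, n=12):
    models = [
        GeneModel(f"g{i}", "chr1", i * 1000, i * 1000 + 400, "+",
                  exons=[(i * 1000, i * 1000 + 400)])
        for i in range(n)
    ]
    assign_ranks(models)
    return models, [f"g{i}" for i in family_positions]


class TestTandem:
    def test_adjacent_family_pair_called(self):
        models, fam = adjacency_genome([7, 8])
        (ev,) = fs.detect_tandem(models, fam)
        assert (ev.gene_a, ev.gene_b, ev.kind) == ("g7", "g8", "tandem")

    def test_intervening_gene_blocks_call(self):
        models, fam = adjacency_genome([7, 9])
        assert fs.detect_tandem(models, fam) == []

    def test_five_gene_array_gives_four_pairs(self):
        models, fam = adjacency_genome([3, 4, 5, 6, 7])
        events = fs.detect_tandem(models, fam)
        assert len(events) == 4
        assert all(e.chromosome_a == e.chromosome_b == "chr1" for e in events)

    def test_planted_arrays_recovered(self, small_genome):
        cfg, models, proteins, truth = small_genome
        events = fs.detect_tandem(models, sorted(truth.family))
        assert len(events) == sum(s - 1 for s in cfg.array_sizes)


class TestSegmental:
    def test_planted_blocks_recovered_with_exact_support(self, small_genome):
        cfg, models, proteins, truth = small_genome
        sim = fs.pairwise_similarity(proteins)
        pairs = [(b["gene_a"], b["gene_b"]) for b in truth.segmental_blocks]
        events = fs.detect_segmental(
            models, pairs, sim, window=cfg.window, threshold=5
        )
        accepted = {(e.gene_a, e.gene_b): e.anchor_support for e in events}
        for block in truth.segmental_blocks:
            key = (block["gene_a"], block["gene_b"])
            if block["anchors"] > 5:
                assert accepted[key] == block["anchors"]
            else:
                assert key not in accepted  # strict >5: 5 anchors is rejected

    def test_locality_label(self, small_genome):
        cfg, models, proteins, truth = small_genome
        sim = fs.pairwise_similarity(proteins)
        pairs = [(b["gene_a"], b["gene_b"]) for b in truth.segmental_blocks]
        by_id = {m.gene_id: m for m in models}
        for e in fs.detect_segmental(models, pairs, sim, window=cfg.window, threshold=5):
            same = by_id[e.gene_a].chromosome == by_id[e.gene_b].chromosome
            assert e.locality == ("intra" if same else "inter")

    def test_default_candidates_include_planted_blocks(self, small_genome):
        cfg, models, proteins, truth = small_genome
        sim = fs.pairwise_similarity(proteins)
        cands = {frozenset(p) for p in default_candidate_pairs(sorted(truth.family), sim)}
        for b in truth.segmental_blocks:
            assert frozenset((b["gene_a"], b["gene_b"])) in cands

    def test_window_must_cover_threshold(self, small_genome):
        cfg, models, proteins, truth = small_genome
        sim = fs.pairwise_similarity(proteins)
        with pytest.raises(DuplicationError):
            fs.detect_segmental(models, [], sim, window=3, threshold=5)
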