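"""Tandem and segmental duplication inference.

Tandem duplicates are family paralogs in strict physical adjacency: same
chromosome, consecutive gene ranks, no intervening annotated gene. Segmental
duplicates are family paralogs whose flanking neighborhoods are conserved:
reciprocal best hits (RBH) between the two flank sets act as orthologous
anchors, and a pair is called segmental when its anchor support strictly
exceeds a threshold (default >5, i.e. at least 6 anchors).

Pairwise protein similarity is Smith–Waterman local alignment (BLOSUM62,
affine gaps: a gap of length L costs open + extend*L), standing in for a
BLASTP all-vs-all. Scores are computed lazily and cached, so genome-scale
inputs only pay for the pairs an analysis actually touches.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_map import GeneModel

__all__ = [
    "AlignParams",
    "SimilarityMatrix",
    "DuplicationEvent",
    "DuplicationError",
    "pairwise_similarity",
    "reciprocal_best_hits",
    "detect_tandem",
    "detect_segmental",
    "default_candidate_pairs",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class DuplicationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    """Local-alignment scoring parameters (gap of length L costs open + extend*L)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


class SimilarityMatrix:
    """Lazy, cached pairwise local-alignment score matrix.

    Symmetric by construction (one score per unordered pair); the diagonal is
    each protein's self-score, which is the maximum of its row because a
    local alignment of a sequence with itself contains any local alignment
    with another sequence.
    """

    def __init__(self, sequences: dict[str, str], params: AlignParams | None = None):
        if params is None:
            params = AlignParams()
        for pid, seq in sequences.items():
            if not seq:
                raise DuplicationError(f"empty sequence for {pid}")
            bad = set(seq.upper()) - STANDARD_AA
            if bad:
                raise DuplicationError(
                    f"{pid}: non-standard residue(s) {sorted(bad)}"
                )
        self.sequences = {pid: seq.upper() for pid, seq in sequences.items()}
        self.params = params
        self._cache: dict[frozenset, float] = {}
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(params.matrix)
        # Biopython charges open_gap_score at the first gap position, so
        # cost(L) = open + extend*L maps to open_gap_score = -(open + extend).
        self._aligner.open_gap_score = -(params.gap_open + params.gap_extend)
        self._aligner.extend_gap_score = -params.gap_extend

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def score(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._cache:
            self._cache[key] = float(
                self._aligner.score(self.sequences[a], self.sequences[b])
            )
        return self._cache[key]

    def dense(self, ids: list[str] | None = None) -> "pd.DataFrame":
        import pandas as pd

        if ids is None:
            ids = self.ids
        data = [[self.score(a, b) for b in ids] for a in ids]
        return pd.DataFrame(data, index=ids, columns=ids)


def pairwise_similarity(
    sequences: dict[str, str], params: AlignParams | None = None
) -> SimilarityMatrix:
    """Build the (lazy) all-vs-all local-alignment similarity matrix."""
    if len(sequences) < 2:
        raise DuplicationError("need at least 2 sequences")
    return SimilarityMatrix(sequences, params)


@dataclass(frozen=True)
class DuplicationEvent:
    kind: str  # tandem | segmental
    gene_a: str
    gene_b: str
    chromosome_a: str
    chromosome_b: str
    locality: str | None = None  # intra | inter (segmental only)
    anchor_support: int | None = None  # segmental only
    effective_window: int | None = None  # smallest flank actually available


def reciprocal_best_hits(
    sim: SimilarityMatrix,
    set_a: list[str],
    set_b: list[str],
    min_score: float = 0.0,
) -> list[tuple[str, str]]:
    """RBH pairs between two disjoint id sets.

    (a, b) is reported iff b is a's best hit in set_b and a is b's best hit in
    set_a; ties break to the lexicographically smallest id, making the output
    deterministic and order-independent. Hits scoring below ``min_score`` are
    ignored entirely (they are "no hit", the way an all-vs-all search drops
    insignificant alignments).
    """
    sa, sb = sorted(set(set_a)), sorted(set(set_b))
    if set(sa) & set(sb):
        raise DuplicationError("set_a and set_b must be disjoint")

    def best(query: str, targets: list[str]) -> str | None:
        scored = [(t, sim.score(query, t)) for t in targets]
        scored = [(t, s) for t, s in scored if s >= min_score]
        if not scored:
            return None
        top = max(s for _, s in scored)
        return min(t for t, s in scored if s == top)

    pairs = []
    for a in sa:
        b = best(a, sb)
        if b is not None and best(b, sa) == a:
            pairs.append((a, b))
    return pairs


def detect_tandem(
    genes: list[GeneModel], family_ids: list[str], sim: SimilarityMatrix | None = None
) -> list[DuplicationEvent]:
    """Tandem events: family pairs with consecutive ranks on one chromosome.

    Strict adjacency — an intervening non-family gene breaks the pair. ``sim``
    is accepted for interface symmetry; adjacency alone defines the call.
    """
    fam = set(family_ids)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id in fam:
            by_chrom.setdefault(g.chromosome, []).append(g)
    events = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda g: g.rank)
        for g1, g2 in zip(members, members[1:]):
            if g2.rank - g1.rank == 1:
                events.append(
                    DuplicationEvent(
                        kind="tandem",
                        gene_a=g1.gene_id,
                        gene_b=g2.gene_id,
                        chromosome_a=chrom,
                        chromosome_b=chrom,
                    )
                )
    return events


def _flanks(
    ordered: dict[str, list[GeneModel]], gene: GeneModel, window: int, exclude: set[str]
) -> list[str]:
    chrom_genes = ordered[gene.chromosome]
    left = [g.gene_id for g in chrom_genes[max(0, gene.rank - window) : gene.rank]]
    right = [g.gene_id for g in chrom_genes[gene.rank + 1 : gene.rank + 1 + window]]
    return [gid for gid in left + right if gid not in exclude]


def detect_segmental(
    genes: list[GeneModel],
    candidate_pairs: list[tuple[str, str]],
    sim: SimilarityMatrix,
    window: int = 20,
    threshold: int = 5,
    min_anchor_score: float = 60.0,
) -> list[DuplicationEvent]:
    """Segmental events by flanking-anchor micro-synteny.

    For each candidate paralog pair, the ``window`` annotated genes on each
    side of both loci are collected; RBH pairs between the two flank sets
    (scores below ``min_anchor_score`` discarded as non-hits) are the anchors.
    The pair is segmental iff anchor_support > ``threshold`` strictly. A locus
    near a chromosome end simply uses the flanks it has; the smaller effective
    flank size is recorded. Overlap with tandem calls is permitted.
    """
    if window < threshold:
        raise DuplicationError("window must be >= threshold")
    by_id = {g.gene_id: g for g in genes}
    ordered: dict[str, list[GeneModel]] = {}
    for g in genes:
        ordered.setdefault(g.chromosome, []).append(g)
    for chrom in ordered:
        ordered[chrom].sort(key=lambda g: g.rank)
    events = []
    for a_id, b_id in candidate_pairs:
        a, b = by_id[a_id], by_id[b_id]
        pair_ids = {a_id, b_id}
        fa = _flanks(ordered, a, window, exclude=pair_ids)
        fb = _flanks(ordered, b, window, exclude=pair_ids | set(fa))
        support = len(reciprocal_best_hits(sim, fa, fb, min_score=min_anchor_score))
        if support > threshold:
            events.append(
                DuplicationEvent(
                    kind="segmental",
                    gene_a=a_id,
                    gene_b=b_id,
                    chromosome_a=a.chromosome,
                    chromosome_b=b.chromosome,
                    locality="intra" if a.chromosome == b.chromosome else "inter",
                    anchor_support=support,
                    effective_window=min(len(fa), len(fb)) // 2,
                )
            )
    return events


def default_candidate_pairs(
    family_ids: list[str], sim: SimilarityMatrix
) -> list[tuple[str, str]]:
    """Family pairs whose similarity exceeds the median family-pair similarity."""
    pairs = list(combinations(sorted(set(family_ids)), 2))
    if not pairs:
        return []
    scores = {p: sim.score(*p) for p in pairs}
    med = statistics.median(scores.values())
    return [p for p in pairs if scores[p] > med]
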