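"""Subfamily assignment by nearest reference in a labeled panel.

Each query protein is scored (Smith–Waterman local alignment) against every
member of a reference panel carrying subgroup labels (SQUA, DEF/GLO, AG, SEP,
AGL6, ..., MIKC*, Mα, Mγ); the query takes the label of its highest-scoring
reference. This best-hit placement stands in for maximum-likelihood tree
placement: it mirrors how a published family inventory reports a per-gene
best ortholog. The margin (best score minus the best score under any *other*
label) lets callers flag low-confidence assignments instead of trusting the
label blindly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .duplication import AlignParams, SimilarityMatrix

__all__ = ["ReferencePanel", "Assignment", "ClassifyError", "assign_subgroup", "read_panel"]


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    label: str
    sequence: str
    species: str = ""


@dataclass
class ReferencePanel:
    entries: list[ReferenceEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ClassifyError("empty reference panel")
        if any(not e.label for e in self.entries):
            raise ClassifyError("every reference needs a non-empty label")
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ClassifyError("duplicate reference ids")

    @property
    def labels(self) -> set[str]:
        return {e.label for e in self.entries}


@dataclass(frozen=True)
class Assignment:
    query_id: str
    label: str
    best_reference: str | None
    score: float
    margin: float


def read_panel(path: str | Path) -> ReferencePanel:
    """Read a panel FASTA whose headers carry ``label=`` (and optional ``species=``)."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        if "label" not in fields:
            raise ClassifyError(f"panel record {rec.id} lacks a label= attribute")
        entries.append(
            ReferenceEntry(
                ref_id=rec.id,
                label=fields["label"],
                sequence=str(rec.seq),
                species=fields.get("species", ""),
            )
        )
    return ReferencePanel(entries)


def assign_subgroup(
    queries: dict[str, str],
    panel: ReferencePanel,
    params: AlignParams | None = None,
    exclude_self: bool = False,
) -> list[Assignment]:
    """Label each query by its best-scoring panel reference.

    Ties break to the lexicographically smallest reference id. A query with no
    positive similarity to any reference is labeled "unclassified".
    ``exclude_self`` drops a reference whose id equals the query id
    (leave-one-out evaluation of the panel itself).
    """
    if not queries:
        raise ClassifyError("no queries")
    seqs = dict(queries)
    for e in panel.entries:
        seqs.setdefault(e.ref_id, e.sequence)
    sim = SimilarityMatrix(seqs, params)
    out = []
    for qid in sorted(queries):
        refs = [e for e in panel.entries if not (exclude_self and e.ref_id == qid)]
        scored = sorted(
            ((sim.score(qid, e.ref_id), e) for e in refs),
            key=lambda t: (-t[0], t[1].ref_id),
        )
        best_score, best = scored[0]
        if best_score <= 0:
            out.append(Assignment(qid, "unclassified", None, best_score, 0.0))
            continue
        other = [s for s, e in scored if e.label != best.label]
        margin = best_score - other[0] if other else float("inf")
        out.append(Assignment(qid, best.label, best.ref_id, best_score, margin))
    return out
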