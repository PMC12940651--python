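"""Data model and statistics for a curated gene-family table.

The packaged fixture (``famscan/data/table1.tsv``) is a transcription of the
87-member teak (*Tectona grandis*) MADS-box family inventory: one row per gene
with its chromosome, exon count, strand, protein length, isoelectric point,
molecular weight, Type I/II group, closest Arabidopsis ortholog, and subgroup.
This module treats such a table as data — it does not recompute pI/MW from
sequence (see :mod:`famscan.protparam` for that) — and provides the counting,
averaging and range statistics used to summarise a family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator

import pandas as pd

__all__ = [
    "FamilyRecord",
    "FamilyTable",
    "FamilyTableError",
    "load_family_table",
    "packaged_table_path",
    "count_by",
    "group_mean",
    "pi_class",
    "exon_range",
    "summary_report",
]

#: column order expected in the TSV header
COLUMNS = [
    "name",
    "gene_id",
    "chromosome",
    "exon_count",
    "strand",
    "length_aa",
    "pI",
    "mw_da",
    "group",
    "ortholog",
    "ortholog_evalue",
    "subgroup",
    "corrected",
    "partial",
]

GROUPS = ("M-type", "MIKC")


class FamilyTableError(ValueError):
    """Raised for malformed or inconsistent family tables."""


@dataclass(frozen=True)
class FamilyRecord:
    """One gene-family member (one row of the inventory table)."""

    name: str
    gene_id: str
    chromosome: str
    exon_count: int
    strand: str
    length_aa: int
    pI: float
    mw_da: float
    group: str
    ortholog: str
    ortholog_evalue: float
    subgroup: str
    corrected: bool = False
    partial: bool = False

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise FamilyTableError(f"{self.name}: exon_count must be positive")
        if self.length_aa < 1:
            raise FamilyTableError(f"{self.name}: length_aa must be positive")
        if self.mw_da <= 0:
            raise FamilyTableError(f"{self.name}: mw_da must be positive")
        if not 0 < self.pI < 14:
            raise FamilyTableError(f"{self.name}: pI {self.pI} outside (0, 14)")
        if self.group not in GROUPS:
            raise FamilyTableError(f"{self.name}: unknown group {self.group!r}")
        if self.strand not in ("+", "-"):
            raise FamilyTableError(f"{self.name}: strand must be + or -")
        if self.subgroup == "MIKC*" and self.group != "MIKC":
            raise FamilyTableError(f"{self.name}: MIKC* subgroup implies MIKC group")
        if self.subgroup in ("α", "γ") and self.group != "M-type":
            raise FamilyTableError(
                f"{self.name}: subgroup {self.subgroup} implies M-type group"
            )

    @property
    def unanchored(self) -> bool:
        """True when the gene sits on an unplaced scaffold rather than a chromosome."""
        return self.chromosome.startswith("Un")


@dataclass
class FamilyTable:
    """Ordered collection of :class:`FamilyRecord` with unique gene names."""

    records: list[FamilyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FamilyTableError(f"duplicate gene names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FamilyRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> FamilyRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)


def packaged_table_path() -> Path:
    """Path of the packaged 87-gene family inventory TSV."""
    return Path(str(resources.files("famscan").joinpath("data/table1.tsv")))


def load_family_table(path: str | Path | None = None) -> FamilyTable:
    """Load a family inventory TSV.

    With no argument, loads the packaged 87-gene table. The file must be
    tab-delimited UTF-8 with a header row naming every :data:`COLUMNS` entry
    ("." decimal separator). ``corrected``/``partial`` are 0/1 flags.
    """
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FamilyTableError(f"missing column(s): {', '.join(missing)}")
    records = [
        FamilyRecord(
            name=row["name"],
            gene_id=row["gene_id"],
            chromosome=row["chromosome"],
            exon_count=int(row["exon_count"]),
            strand=row["strand"],
            length_aa=int(row["length_aa"]),
            pI=float(row["pI"]),
            mw_da=float(row["mw_da"]),
            group=row["group"],
            ortholog=row["ortholog"],
            ortholog_evalue=float(row["ortholog_evalue"]),
            subgroup=row["subgroup"],
            corrected=row["corrected"] == "1",
            partial=row["partial"] == "1",
        )
        for _, row in df.iterrows()
    ]
    return FamilyTable(records)


Predicate = Callable[[FamilyRecord], bool]


def count_by(table: FamilyTable, predicate: Predicate) -> int:
    """Number of records satisfying ``predicate``."""
    return sum(1 for r in table if predicate(r))


def _select(
    table: FamilyTable, selector: Predicate | None, exclude_partial: bool
) -> list[FamilyRecord]:
    recs = [r for r in table if selector is None or selector(r)]
    if exclude_partial:
        recs = [r for r in recs if not r.partial]
    return recs


def group_mean(
    table: FamilyTable,
    fieldname: str,
    selector: Predicate | None = None,
    exclude_partial: bool = False,
) -> float:
    """Arithmetic mean of ``pI`` or ``mw_da`` over the selected records.

    ``exclude_partial`` drops records flagged as partial gene models before
    averaging; whether a published aggregate includes partials varies, so the
    caller decides explicitly.
    """
    if fieldname not in ("pI", "mw_da"):
        raise FamilyTableError(f"group_mean supports pI/mw_da, not {fieldname!r}")
    recs = _select(table, selector, exclude_partial)
    if not recs:
        raise FamilyTableError("no records matched the selection")
    vals = [getattr(r, fieldname) for r in recs]
    return sum(vals) / len(vals)


def pi_class(pI: float) -> str:
    """Classify an isoelectric point as acidic (<6.5), neutral (6.5–7.5) or basic (>7.5)."""
    if not 0 < pI < 14:
        raise FamilyTableError(f"pI {pI} outside (0, 14)")
    if pI < 6.5:
        return "acidic"
    if pI <= 7.5:
        return "neutral"
    return "basic"


def exon_range(
    table: FamilyTable, group: str, exclude_partial: bool = False
) -> tuple[int, int]:
    """(min, max) exon count over one group, optionally dropping partial models."""
    recs = _select(table, lambda r: r.group == group, exclude_partial)
    if not recs:
        raise FamilyTableError(f"no records in group {group!r}")
    counts = [r.exon_count for r in recs]
    return min(counts), max(counts)


def chromosome_counts(table: FamilyTable) -> dict[str, int]:
    """Per-chromosome record counts (unanchored scaffolds under their own labels)."""
    out: dict[str, int] = {}
    for r in table:
        out[r.chromosome] = out.get(r.chromosome, 0) + 1
    return out


def summary_report(table: FamilyTable) -> dict:
    """Aggregate statistics of a family table as a JSON-ready dict.

    Means follow the conventions used for the teak inventory: the MIKC^C pI
    mean includes partial models, the MIKC^C mass mean and the exon maxima
    exclude them.
    """
    mikc_star = lambda r: r.subgroup == "MIKC*"  # noqa: E731
    mikc_c = lambda r: r.group == "MIKC" and r.subgroup != "MIKC*"  # noqa: E731
    m_type = lambda r: r.group == "M-type"  # noqa: E731
    pic = {"acidic": 0, "neutral": 0, "basic": 0}
    for r in table:
        pic[pi_class(r.pI)] += 1
    return {
        "n_records": len(table),
        "counts": {
            "MIKC": count_by(table, lambda r: r.group == "MIKC"),
            "M-type": count_by(table, m_type),
            "unanchored": count_by(table, lambda r: r.unanchored),
            "by_chromosome": chromosome_counts(table),
            "pi_class": pic,
        },
        "means": {
            "pI": {
                "MIKC*": group_mean(table, "pI", mikc_star),
                "MIKC^C": group_mean(table, "pI", mikc_c),
                "M-type": group_mean(table, "pI", m_type),
            },
            "mw_kda": {
                "MIKC*": group_mean(table, "mw_da", mikc_star) / 1000.0,
                "MIKC^C": group_mean(table, "mw_da", mikc_c, exclude_partial=True)
                / 1000.0,
                "M-type": group_mean(table, "mw_da", m_type) / 1000.0,
            },
        },
        "exon_ranges": {
            "MIKC": exon_range(table, "MIKC", exclude_partial=True),
            "M-type": exon_range(table, "M-type"),
        },
    }
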