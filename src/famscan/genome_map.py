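"""Genome-annotation structure analysis: chromosome mapping, clusters, exons.

Coordinates are 0-based half-open internally; the GFF3 boundary (1-based,
inclusive) is converted in exactly one place each way (`parse_gff3` /
`write_gff3`). Gene order along a chromosome is captured as an integer
``rank`` (0-based, by start coordinate), which is what adjacency-based
analyses (tandem duplication, clustering) consume — strand plays no role in
adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

__all__ = [
    "GeneModel",
    "GeneCluster",
    "GenomeMapError",
    "parse_gff3",
    "write_gff3",
    "chromosome_distribution",
    "find_clusters",
    "exon_stats",
    "to_bed",
]

LONG_INTRON_BP = 10_000


class GenomeMapError(ValueError):
    pass


@dataclass
class GeneModel:
    """An annotated gene: span, strand and exon intervals (0-based half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    rank: int = -1  # ordinal along the chromosome, assigned by parse/layout

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeMapError(f"{self.gene_id}: start must be < end")
        if not self.exons:
            raise GenomeMapError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise GenomeMapError(f"{self.gene_id}: empty exon ({a},{b})")
            if prev_end is not None and a < prev_end:
                raise GenomeMapError(f"{self.gene_id}: overlapping exons")
            prev_end = b

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_lengths(self) -> list[int]:
        return [
            self.exons[i + 1][0] - self.exons[i][1] for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GeneCluster:
    """A run of >=2 family genes close together on one chromosome."""

    chromosome: str
    member_ids: list[str]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise GenomeMapError("a cluster needs at least 2 members")


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Set ``rank`` per chromosome by start coordinate (in place); returns input."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        for i, g in enumerate(sorted(members, key=lambda g: (g.start, g.gene_id))):
            g.rank = i
    return genes


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features of a GFF3 file into gene models.

    One model per gene: the first mRNA by coordinate is canonical. GFF3
    1-based inclusive coordinates become 0-based half-open. Exons whose parent
    cannot be resolved are skipped with a warning; malformed coordinates raise
    a format error naming the offending line.
    """
    path = Path(path)
    _check_coordinates(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    known_parents = {f.id for f in db.all_features() if f.featuretype in ("gene", "mRNA")}
    for exon in db.features_of_type("exon"):
        for parent in exon.attributes.get("Parent", []):
            if parent not in known_parents:
                warnings.warn(
                    f"exon {exon.id or exon.start} has unresolvable parent {parent}; skipped"
                )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA"), key=lambda f: (f.start, f.id)
        )
        if mrnas:
            exon_source = mrnas[0]
        else:
            exon_source = gene  # tolerate exons hung directly off the gene
        exons = [
            (f.start - 1, f.end)
            for f in db.children(exon_source, featuretype="exon")
        ]
        if not exons:
            warnings.warn(f"gene {gene.id} has no exons; skipped")
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
            )
        )
    return assign_ranks(models)


def _check_coordinates(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise GenomeMapError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GenomeMapError(
                    f"{path}:{lineno}: malformed coordinate ({parts[3]!r}, {parts[4]!r})"
                ) from exc
            if start < 1 or end < start:
                raise GenomeMapError(f"{path}:{lineno}: invalid range {start}-{end}")


def write_gff3(models: list[GeneModel], path: str | Path, source: str = "famscan") -> None:
    """Serialize gene models as GFF3 (gene -> mRNA -> exon, ID/Parent links)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chromosome}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={gid}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n"
                )


def chromosome_distribution(
    genes: list[GeneModel], family_ids: list[str]
) -> dict[str, int]:
    """Per-chromosome counts of family genes; totals conserve len(family_ids)."""
    by_id = {g.gene_id: g for g in genes}
    unknown = [i for i in family_ids if i not in by_id]
    if unknown:
        raise GenomeMapError(f"unknown family id(s): {', '.join(sorted(unknown))}")
    counts: dict[str, int] = {}
    for fid in family_ids:
        chrom = by_id[fid].chromosome
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts


def find_clusters(
    genes: list[GeneModel], family_ids: list[str], max_intervening: int = 0
) -> list[GeneCluster]:
    """Maximal runs of family genes separated by <= max_intervening non-family genes.

    With the default ``max_intervening=0`` only strictly consecutive family
    genes cluster. Clusters are disjoint and need >=2 members.
    """
    if max_intervening < 0:
        raise GenomeMapError("max_intervening must be >= 0")
    fam = set(family_ids)
    members = [g for g in genes if g.gene_id in fam]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in members:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        run: list[GeneModel] = []
        for g in sorted(by_chrom[chrom], key=lambda g: g.rank):
            if run and g.rank - run[-1].rank <= max_intervening + 1:
                run.append(g)
            else:
                if len(run) >= 2:
                    clusters.append(_close_run(chrom, run))
                run = [g]
        if len(run) >= 2:
            clusters.append(_close_run(chrom, run))
    return clusters


def _close_run(chrom: str, run: list[GeneModel]) -> GeneCluster:
    return GeneCluster(
        chromosome=chrom,
        member_ids=[g.gene_id for g in run],
        span=(min(g.start for g in run), max(g.end for g in run)),
    )


def exon_stats(gene: GeneModel) -> tuple[int, list[int], bool]:
    """(exon_count, intron_lengths, any intron longer than 10 kb)."""
    introns = gene.intron_lengths
    return gene.exon_count, introns, any(i > LONG_INTRON_BP for i in introns)


def to_bed(genes: list[GeneModel], family_ids: list[str], path: str | Path) -> None:
    """Write family genes as BED6 (0-based half-open, matching internal coords)."""
    fam = set(family_ids)
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            if g.gene_id in fam:
                fh.write(
                    f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
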