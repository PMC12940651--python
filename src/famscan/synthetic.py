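"""Seeded synthetic genomes, proteomes and expression matrices with planted truth.

The generator emulates the statistical structure a gene-family pipeline
consumes, without any download:

* Type II family proteins carry a planted 57-aa MADS-like domain followed by
  the three 29-aa K segments and get multi-exon (5–8) gene models; Type I
  proteins carry the MADS domain only and get 1–2 exons — the bimodal
  exon-count structure of real plant MADS inventories.
* Tandem arrays are runs of adjacent family genes (paralog copies with no
  intervening gene).
* Segmental blocks are duplicated neighborhoods: a family gene plus exactly
  ``anchors_per_block`` flanking genes copied (optionally mutated) to a second
  locus, so flanking-anchor micro-synteny recovers the block with a known
  anchor count.
* Expression matrices give every gene a log-normal baseline, multiplied by
  group-by-tissue fold changes (default: MIKC genes elevated in flower), with
  Gaussian noise on the log scale.

Planted domains are sampled from the packaged profile consensus sequences
with per-site substitution at ``mutation_rate``, tying the generator to the
scanner without sharing code paths. All randomness flows from one integer
seed through one generator stream; identical seeds give byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genome_map import GeneModel, assign_ranks, write_gff3
from .profiles import AA_ORDER, CONSENSUS, robinson_background

__all__ = [
    "GenomeConfig",
    "SyntheticTruth",
    "SyntheticDataError",
    "generate_genome",
    "generate_expression",
    "write_genome_files",
    "write_fasta",
]

MIKC_SUBGROUPS = [
    "SQUA (A)", "DEF/GLO (B)", "AG (C/D)", "SEP (E)", "AGL17 (ANR1)",
    "SOC1/TM3", "STMADS11 (SVP)", "AGL6", "FLC", "MIKC*",
]
MTYPE_SUBGROUPS = ["α", "γ"]


class SyntheticDataError(ValueError):
    pass


@dataclass
class GenomeConfig:
    """Study conditions for one synthetic genome."""

    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    n_family: int = 20
    fraction_typeII: float = 0.6
    n_tandem_arrays: int = 3
    array_sizes: tuple = (2, 3, 5)
    n_segmental_blocks: int = 4
    anchors_per_block: tuple = (4, 6, 8, 12)
    mutation_rate: float = 0.0
    seed: int = 42
    window: int = 20  # flank window the planted blocks are sized against

    def __post_init__(self) -> None:
        if isinstance(self.array_sizes, int):
            self.array_sizes = (self.array_sizes,) * self.n_tandem_arrays
        if isinstance(self.anchors_per_block, int):
            self.anchors_per_block = (self.anchors_per_block,) * self.n_segmental_blocks
        self.array_sizes = tuple(self.array_sizes)
        self.anchors_per_block = tuple(self.anchors_per_block)
        if len(self.array_sizes) != self.n_tandem_arrays:
            raise SyntheticDataError("array_sizes length must equal n_tandem_arrays")
        if len(self.anchors_per_block) != self.n_segmental_blocks:
            raise SyntheticDataError(
                "anchors_per_block length must equal n_segmental_blocks"
            )
        if not 0 <= self.mutation_rate < 0.5:
            raise SyntheticDataError("mutation_rate must be in [0, 0.5)")
        if any(s < 2 for s in self.array_sizes):
            raise SyntheticDataError("tandem arrays need at least 2 members")
        if any(a < 1 for a in self.anchors_per_block):
            raise SyntheticDataError("segmental blocks need at least 1 anchor")
        if any(a > 2 * self.window for a in self.anchors_per_block):
            raise SyntheticDataError("anchors_per_block cannot exceed 2*window")
        planted = sum(self.array_sizes) + 2 * self.n_segmental_blocks
        if self.n_family < planted:
            raise SyntheticDataError(
                f"n_family={self.n_family} cannot hold {planted} planted family genes "
                f"(sum of array sizes + 2 per segmental block)"
            )


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator planted."""

    family: dict  # gene_id -> {"type": TypeI|TypeII, "subgroup": str}
    domains: dict  # protein_id -> [(profile_name, start, end), ...]
    tandem_arrays: list  # [[gene_id, ...], ...] ordered along the chromosome
    segmental_blocks: list  # [{"gene_a", "gene_b", "anchors"}, ...]
    expression_effects: dict = field(default_factory=dict)  # group -> tissue -> fold

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["domains"] = {
            k: [tuple(t) for t in v] for k, v in d.get("domains", {}).items()
        }
        return cls(**d)


def _random_protein(rng: np.random.Generator, bg: np.ndarray, lo=80, hi=160) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA_ORDER), size=n, p=bg))


def _mutate(seq: str, rate: float, rng: np.random.Generator, bg: np.ndarray) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    mask = rng.random(len(chars)) < rate
    repl = rng.choice(list(AA_ORDER), size=len(chars), p=bg)
    for i in np.flatnonzero(mask):
        chars[i] = str(repl[i])
    return "".join(chars)


def _family_protein(
    type_call: str, rate: float, rng: np.random.Generator, bg: np.ndarray
) -> tuple[str, list[tuple[str, int, int]]]:
    """Build one family protein and the planted domain coordinates."""
    parts = ["M" + _random_protein(rng, bg, 8, 12)]
    domains = []
    pos = len(parts[0])
    mads = _mutate(CONSENSUS["MADS"], rate, rng, bg)
    domains.append(("MADS", pos, pos + len(mads)))
    parts.append(mads)
    pos += len(mads)
    if type_call == "TypeII":
        for name in ("K1", "K2", "K3"):
            linker = _random_protein(rng, bg, 4, 10)
            parts.append(linker)
            pos += len(linker)
            seg = _mutate(CONSENSUS[name], rate, rng, bg)
            domains.append((name, pos, pos + len(seg)))
            parts.append(seg)
            pos += len(seg)
        parts.append(_random_protein(rng, bg, 15, 30))
    else:
        parts.append(_random_protein(rng, bg, 25, 60))
    return "".join(parts), domains


def _gene_models(
    chrom_names: list[str],
    slots: dict[tuple[int, int], dict],
    cfg: GenomeConfig,
    rng: np.random.Generator,
) -> list[GeneModel]:
    models = []
    for ci, chrom in enumerate(chrom_names):
        offset = 1000
        for pos in range(cfg.genes_per_chromosome):
            info = slots[(ci, pos)]
            n_ex = info["n_exons"]
            exons = []
            cursor = offset
            for k in range(n_ex):
                ex_len = int(rng.integers(100, 301))
                exons.append((cursor, cursor + ex_len))
                cursor += ex_len
                if k < n_ex - 1:
                    cursor += int(rng.integers(200, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                GeneModel(
                    gene_id=info["gene_id"],
                    chromosome=chrom,
                    start=offset,
                    end=cursor,
                    strand=strand,
                    exons=exons,
                )
            )
            offset = cursor + int(rng.integers(200, 801))
    return assign_ranks(models)


def generate_genome(
    config: GenomeConfig,
) -> tuple[list[GeneModel], dict[str, str], SyntheticTruth]:
    """Generate (gene models, proteome, truth) for one synthetic genome."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bg = robinson_background()
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    # Candidate feature sites: separated enough that flank windows of distinct
    # planted features never overlap (2*window plus the largest array).
    margin = cfg.window + max((*cfg.array_sizes, 0)) + 5
    sep = 2 * cfg.window + max((*cfg.array_sizes, 0)) + 10
    sites = [
        (ci, pos)
        for ci in range(cfg.n_chromosomes)
        for pos in range(margin, cfg.genes_per_chromosome - margin, sep)
    ]
    n_single = cfg.n_family - sum(cfg.array_sizes) - 2 * cfg.n_segmental_blocks
    needed = cfg.n_tandem_arrays + 2 * cfg.n_segmental_blocks + n_single
    if len(sites) < needed:
        raise SyntheticDataError(
            f"genome too small: {needed} feature sites needed, only {len(sites)} fit "
            f"({cfg.n_chromosomes} x {cfg.genes_per_chromosome} genes, window {cfg.window})"
        )
    order = rng.permutation(len(sites))
    picked = [sites[i] for i in order[:needed]]

    # slot bookkeeping: every (chrom index, position) starts as background
    slots: dict[tuple[int, int], dict] = {}
    for ci in range(cfg.n_chromosomes):
        for pos in range(cfg.genes_per_chromosome):
            gid = f"{chrom_names[ci]}_g{pos:04d}"
            slots[(ci, pos)] = {
                "gene_id": gid,
                "protein": None,  # filled later
                "n_exons": int(rng.integers(1, 6)),
                "family": None,
            }

    truth = SyntheticTruth(family={}, domains={}, tandem_arrays=[], segmental_blocks=[])
    type_cycle = {"TypeII": 0, "TypeI": 0}

    def plant_family(ci: int, pos: int, type_call: str, prototype=None):
        """Place one family gene; returns (gene_id, protein, domains)."""
        if prototype is None:
            protein, domains = _family_protein(type_call, cfg.mutation_rate, rng, bg)
        else:
            protein = _mutate(prototype[0], cfg.mutation_rate, rng, bg)
            domains = prototype[1]
        info = slots[(ci, pos)]
        info["protein"] = protein
        info["family"] = type_call
        info["n_exons"] = (
            int(rng.integers(5, 9)) if type_call == "TypeII" else int(rng.integers(1, 3))
        )
        subs = MIKC_SUBGROUPS if type_call == "TypeII" else MTYPE_SUBGROUPS
        sub = subs[type_cycle[type_call] % len(subs)]
        type_cycle[type_call] += 1
        truth.family[info["gene_id"]] = {"type": type_call, "subgroup": sub}
        truth.domains[info["gene_id"]] = list(domains)
        return info["gene_id"], protein, domains

    def draw_type() -> str:
        return "TypeII" if rng.random() < cfg.fraction_typeII else "TypeI"

    site_iter = iter(picked)

    # tandem arrays: adjacent copies of one prototype
    for size in cfg.array_sizes:
        ci, pos = next(site_iter)
        t = draw_type()
        proto_seq, proto_dom = _family_protein(t, cfg.mutation_rate, rng, bg)
        members = []
        for k in range(size):
            gid, _, _ = plant_family(ci, pos + k, t, prototype=(proto_seq, proto_dom))
            members.append(gid)
        truth.tandem_arrays.append(members)

    # segmental blocks: duplicated family gene + exactly `anchors` copied flanks
    for anchors in cfg.anchors_per_block:
        (ca, pa), (cb, pb) = next(site_iter), next(site_iter)
        t = draw_type()
        proto_seq, proto_dom = _family_protein(t, cfg.mutation_rate, rng, bg)
        gid_a, _, _ = plant_family(ca, pa, t, prototype=(proto_seq, proto_dom))
        gid_b, _, _ = plant_family(cb, pb, t, prototype=(proto_seq, proto_dom))
        kl = anchors // 2
        kr = anchors - kl
        offsets = [-(i + 1) for i in range(kl)] + [i + 1 for i in range(kr)]
        for off in offsets:
            original = _random_protein(rng, bg, 100, 160)
            slots[(ca, pa + off)]["protein"] = original
            slots[(cb, pb + off)]["protein"] = _mutate(
                original, cfg.mutation_rate, rng, bg
            )
        truth.segmental_blocks.append(
            {"gene_a": gid_a, "gene_b": gid_b, "anchors": int(anchors)}
        )

    # remaining singleton family genes
    for _ in range(n_single):
        ci, pos = next(site_iter)
        plant_family(ci, pos, draw_type())

    # background proteins for everything unfilled
    for key in slots:
        if slots[key]["protein"] is None:
            slots[key]["protein"] = _random_protein(rng, bg)

    models = _gene_models(chrom_names, slots, cfg, rng)
    proteins = {info["gene_id"]: info["protein"] for info in slots.values()}
    return models, proteins, truth


DEFAULT_TISSUES = ("root", "seedling", "leaf", "flower", "stem", "branch")
DEFAULT_EFFECTS = {"MIKC": {"flower": 10.0}}


def generate_expression(
    truth: SyntheticTruth,
    tissues: tuple = DEFAULT_TISSUES,
    effect_map: dict | None = None,
    noise_sd: float = 0.3,
    seed: int = 42,
) -> ExpressionMatrix:
    """FPKM matrix over the truth's family genes with planted tissue effects.

    ``effect_map`` maps a group (MIKC / M-type, matching TypeII / TypeI) to
    tissue fold changes; unmentioned combinations get fold 1. Baselines are
    log-normal (median ~20 FPKM, sigma 1); noise is Gaussian on the log scale.
    """
    if not tissues:
        raise SyntheticDataError("tissues must be non-empty")
    if noise_sd < 0:
        raise SyntheticDataError("noise_sd must be >= 0")
    if effect_map is None:
        effect_map = DEFAULT_EFFECTS
    rng = np.random.default_rng(seed)
    genes = sorted(truth.family)
    group = {
        g: ("MIKC" if truth.family[g]["type"] == "TypeII" else "M-type") for g in genes
    }
    baseline = {g: float(rng.lognormal(math.log(20.0), 1.0)) for g in genes}
    data = {}
    for tissue in tissues:
        col = []
        for g in genes:
            fold = effect_map.get(group[g], {}).get(tissue, 1.0)
            val = baseline[g] * fold
            if noise_sd > 0:
                val *= math.exp(float(rng.normal(0.0, noise_sd)))
            col.append(val)
        data[tissue] = col
    truth.expression_effects = effect_map
    return ExpressionMatrix(pd.DataFrame(data, index=genes), "FPKM")


def write_fasta(proteins: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n")
            seq = proteins[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_files(
    models: list[GeneModel],
    proteins: dict[str, str],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genome.gff3, proteome.fa and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "genome.gff3",
        "fasta": outdir / "proteome.fa",
        "truth": outdir / "truth.json",
    }
    write_gff3(models, paths["gff3"])
    write_fasta(proteins, paths["fasta"])
    truth.to_json(paths["truth"])
    return paths
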