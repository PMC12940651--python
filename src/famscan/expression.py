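"""Expression normalization (FPKM -> TPM) and tissue summaries.

TPM rescales each sample so its values sum to one million:

    TPM_gene = FPKM_gene / sum(FPKM over the sample) * 1e6

making abundances comparable across samples. Zero-expression genes are kept
(absence of expression is itself informative); NaN inputs are rejected rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionError",
    "read_matrix",
    "fpkm_to_tpm",
    "expression_summary",
    "heatmap_export",
]

TPM_TOTAL = 1e6


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance table with an explicit unit (FPKM or TPM)."""

    values: pd.DataFrame  # rows: gene ids, columns: sample labels
    unit: str  # FPKM | TPM

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ExpressionError(f"unknown unit {self.unit!r}")
        if self.values.isna().any().any():
            raise ExpressionError("NaN values are not allowed")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative abundances are not allowed")
        if self.unit == "TPM":
            sums = self.values.sum(axis=0)
            off = sums[~np.isclose(sums, TPM_TOTAL, rtol=1e-6)]
            if len(off):
                raise ExpressionError(
                    f"TPM columns must sum to 1e6; off: {list(off.index)}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path: str | Path, unit: str = "FPKM") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), unit)


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert an FPKM matrix to TPM (per-column rescale to 1e6)."""
    if matrix.unit != "FPKM":
        raise ExpressionError(f"expected FPKM input, got {matrix.unit}")
    sums = matrix.values.sum(axis=0)
    zero = [s for s in matrix.samples if sums[s] == 0]
    if zero:
        raise ExpressionError(f"all-zero sample column(s): {', '.join(zero)}")
    return ExpressionMatrix(matrix.values / sums * TPM_TOTAL, "TPM")


def expression_summary(
    matrix: ExpressionMatrix, gene_groups: dict[str, list[str]]
) -> dict:
    """Per-group per-sample mean abundance and the top family gene per sample.

    ``gene_groups`` maps a group label (e.g. MIKC, M-type, or a subgroup) to
    row ids. The top gene per sample is taken over the union of all groups;
    ties break to the lexicographically smallest gene id.
    """
    missing = sorted(
        {g for ids in gene_groups.values() for g in ids} - set(matrix.genes)
    )
    if missing:
        raise ExpressionError(f"group gene(s) not in matrix: {', '.join(missing)}")
    group_means = pd.DataFrame(
        {grp: matrix.values.loc[ids].mean(axis=0) for grp, ids in gene_groups.items()}
    ).T  # groups x samples
    family = sorted({g for ids in gene_groups.values() for g in ids})
    fam_vals = matrix.values.loc[family].sort_index()
    top_gene = {
        sample: fam_vals[sample].idxmax()  # idxmax on sorted index -> smallest id wins ties
        for sample in matrix.samples
    }
    return {"group_means": group_means, "top_gene": top_gene}


def heatmap_export(
    matrix: ExpressionMatrix, path: str | Path, transform: str = "none"
) -> None:
    """Write a heatmap-ready TSV; transform 'log2p1' applies log2(value + 1)."""
    if transform not in ("none", "log2p1"):
        raise ExpressionError(f"unknown transform {transform!r}")
    vals = matrix.values if transform == "none" else np.log2(matrix.values + 1.0)
    vals.to_csv(path, sep="\t", index_label="gene")
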