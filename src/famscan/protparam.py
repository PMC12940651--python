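"""Protein physicochemistry: average molecular weight and isoelectric point.

Conventions match the Expasy ProtParam web tool: average (not monoisotopic)
residue masses plus one water per chain, and the Bjellqvist pKa set for the
Henderson–Hasselbalch charge model. The isoelectric point is the unique pH at
which the net charge vanishes; since net charge is strictly decreasing in pH,
bisection on (0, 14) converges unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PkaTable",
    "BJELLQVIST",
    "EMBOSS",
    "ProtParamError",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
]

WATER_DA = 18.0153

#: average residue (amino acid minus water) masses, daltons
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


class ProtParamError(ValueError):
    pass


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values (pH units)."""

    sidechain: dict  # acidic: D E C Y; basic: H K R
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        for res, pka in {
            **self.sidechain,
            "Nterm": self.n_terminus,
            "Cterm": self.c_terminus,
        }.items():
            if not 0 < pka < 14:
                raise ProtParamError(f"pKa for {res} outside (0, 14): {pka}")


BJELLQVIST = PkaTable(
    sidechain={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0},
    n_terminus=7.5,
    c_terminus=3.55,
)

EMBOSS = PkaTable(
    sidechain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5},
    n_terminus=8.6,
    c_terminus=3.6,
)

PKA_SETS = {"bjellqvist": BJELLQVIST, "emboss": EMBOSS}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def _validate(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ProtParamError("empty sequence")
    bad = set(seq) - set(RESIDUE_MASS)
    if bad:
        raise ProtParamError(f"unknown residue(s): {sorted(bad)}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    seq = _validate(seq)
    return sum(RESIDUE_MASS[c] for c in seq) + WATER_DA


def net_charge(seq: str, pH: float, pka: PkaTable = BJELLQVIST) -> float:
    """Net charge (elementary charges) at a given pH, termini included.

    Each basic group contributes 1/(1 + 10^(pH - pKa)); each acidic group
    contributes -1/(1 + 10^(pKa - pH)).
    """
    seq = _validate(seq)
    if not 0 < pH < 14:
        raise ProtParamError(f"pH {pH} outside (0, 14)")
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    neg = 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for c in seq:
        if c in _BASIC:
            pos += 1.0 / (1.0 + 10.0 ** (pH - pka.sidechain[c]))
        elif c in _ACIDIC:
            neg += 1.0 / (1.0 + 10.0 ** (pka.sidechain[c] - pH))
    return pos - neg


def isoelectric_point(
    seq: str, pka: PkaTable = BJELLQVIST, tol: float = 1e-3
) -> float:
    """pH at which the net charge is zero, by bisection to within ``tol``.

    The termini always ionize, so every sequence has at least two ionizable
    groups and a unique zero crossing in (0, 14).
    """
    seq = _validate(seq)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            return mid
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    raise ProtParamError("bisection failed to converge in 100 iterations")
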