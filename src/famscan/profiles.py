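"""Packaged position-specific profiles for the MADS domain and K segments.

The seed sequences here are *synthetic*: fixed, MADS/keratin-like consensus
strings of the canonical lengths (57 aa for the DNA-binding MADS domain, 29 aa
for each of the three K-domain helical segments). They are not derived from
Pfam alignments; they exist so the scanner, the architecture caller and the
synthetic-genome generator share one self-consistent domain vocabulary. Users
with real seed alignments can build their own profiles with
:func:`famscan.domain_scan.build_profile`.
"""

from __future__ import annotations

import numpy as np

#: fixed amino-acid alphabet order used by every profile and scanner array
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Robinson–Robinson background amino-acid frequencies (normalised on load)
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def robinson_background() -> np.ndarray:
    bg = np.array([ROBINSON_FREQS[a] for a in AA_ORDER], dtype=float)
    return bg / bg.sum()


# Synthetic consensus sequences (fixed; see module docstring).
MADS_CONSENSUS = "MGRGRVELKRIENKINRQVTFAKRRNGLLKKAYELSVLCDAEVALIIFSNRGKLYEF"  # 57 aa
K1_CONSENSUS = "ESLERQLESSLKQIRSRKNQLLYDSISEL"  # 29 aa
K2_CONSENSUS = "QLKELQNLEQQLDTALKHIRSRKNQLMHE"  # 29 aa
K3_CONSENSUS = "SISELQKKEKALQEQNNLLAKKVKEKEKE"  # 29 aa

CONSENSUS = {
    "MADS": MADS_CONSENSUS,
    "K1": K1_CONSENSUS,
    "K2": K2_CONSENSUS,
    "K3": K3_CONSENSUS,
}

#: number of seed variants per packaged profile and their substitution rate
_SEED_DEPTH = 8
_SEED_RATE = 0.05
_SEED_SEED = 20250101  # fixed stream so packaged profiles are reproducible


def seed_alignment(name: str, rng: np.random.Generator | None = None) -> list[str]:
    """Deterministic gapless seed alignment for one packaged profile.

    Eight variants of the consensus, each position substituted with
    probability 0.05 by a background-drawn residue.
    """
    cons = CONSENSUS[name]
    if rng is None:
        rng = np.random.default_rng(_SEED_SEED + sum(map(ord, name)))
    bg = robinson_background()
    rows = [cons]
    for _ in range(_SEED_DEPTH - 1):
        chars = list(cons)
        mask = rng.random(len(chars)) < _SEED_RATE
        repl = rng.choice(list(AA_ORDER), size=len(chars), p=bg)
        for i in np.flatnonzero(mask):
            chars[i] = str(repl[i])
        rows.append("".join(chars))
    return rows
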