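"""Family identification by ungapped position-specific profile scanning.

A proteome is searched with log-odds profiles of the 57-aa MADS domain and the
three 29-aa K segments. Statistical significance follows the extreme-value
convention of sequence-database search: the maximal window score of a
background sequence is Gumbel distributed, so after calibrating (mu, lambda)
on randomized background sequences,

    E(s, N) = N * (1 - exp(-exp(-lambda * (s - mu))))

is the expected number of background sequences in a database of size N
reaching score s. Hits with E below a cutoff (default 1e-3) are significant.

The scan is deliberately ungapped: the domains scanned here are fixed-length
blocks, for which a position-specific scoring matrix is adequate and keeps
scoring exactly invertible for calibration. This replaces a profile-HMM
forward/Viterbi search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import AA_INDEX, AA_ORDER, robinson_background, seed_alignment

__all__ = [
    "ProfileMatrix",
    "DomainHit",
    "ArchitectureCall",
    "ProfileError",
    "CalibrationError",
    "build_profile",
    "default_profiles",
    "scan_sequence",
    "calibrate_evalue",
    "call_architecture",
    "hydropathy_flag",
]


class ProfileError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class ProfileMatrix:
    """Log-odds scoring matrix over the 20-aa alphabet with Gumbel calibration."""

    name: str
    weights: np.ndarray  # (length, 20) log2-odds in bits
    background: np.ndarray  # (20,) frequencies summing to 1
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(AA_ORDER):
            raise ProfileError("weights must be (length, 20)")
        if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-9):
            raise ProfileError("background must sum to 1")
        if self.gumbel_lambda is not None and self.gumbel_lambda <= 0:
            raise ProfileError("gumbel_lambda must be positive")

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.weights.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence (sum of per-column maxima)."""
        return float(self.weights.max(axis=1).sum())

    def evalue(self, score: float, database_size: int = 1) -> float:
        """Expected background sequences at or above ``score`` in a database."""
        if not self.calibrated:
            raise CalibrationError(f"profile {self.name} is not calibrated")
        p = -np.expm1(-np.exp(-self.gumbel_lambda * (score - self.gumbel_mu)))
        return float(database_size * p)

    def score_threshold(self, evalue: float, database_size: int = 1) -> float:
        """Smallest score whose E-value is below ``evalue``."""
        if not self.calibrated:
            raise CalibrationError(f"profile {self.name} is not calibrated")
        p = evalue / database_size
        if p >= 1.0:
            return -np.inf
        return self.gumbel_mu - math.log(-math.log1p(-p)) / self.gumbel_lambda


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    profile_name: str
    start: int  # 0-based half-open on the protein
    end: int
    score: float  # bits
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ProfileError("evalue must be non-negative")


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    type_call: str  # TypeI | TypeII | unclassified
    k_segments_found: int
    reannotation_flag: bool
    reason: str = ""


def build_profile(
    seed_alignment: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    name: str = "profile",
) -> ProfileMatrix:
    """Build a log-odds profile from a gapped seed alignment.

    Columns with more than 50% gaps ('-' or '.') are dropped; at least half of
    the columns must survive. Per-column residue frequencies get an additive
    ``pseudocount`` and are converted to log2 odds against ``background``
    (Robinson–Robinson by default).
    """
    if len(seed_alignment) < 2:
        raise ProfileError("seed alignment needs at least 2 sequences")
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ProfileError("aligned rows must all have equal length")
    ncol = lengths.pop()
    if ncol == 0:
        raise ProfileError("empty alignment")
    if background is None:
        background = robinson_background()
    rows = [s.upper() for s in seed_alignment]
    kept_cols = []
    for j in range(ncol):
        col = [r[j] for r in rows]
        gaps = sum(c in "-." for c in col)
        if gaps / len(col) <= 0.5:
            kept_cols.append(j)
    if ncol and len(kept_cols) / ncol < 0.5:
        raise ProfileError("fewer than 50% of columns are non-gap")
    weights = np.zeros((len(kept_cols), len(AA_ORDER)))
    for out_j, j in enumerate(kept_cols):
        counts = np.zeros(len(AA_ORDER))
        n = 0
        for r in rows:
            c = r[j]
            if c in "-.":
                continue
            if c not in AA_INDEX:
                raise ProfileError(f"illegal residue {c!r} in column {j}")
            counts[AA_INDEX[c]] += 1
            n += 1
        freqs = (counts + pseudocount) / (n + pseudocount * len(AA_ORDER))
        with np.errstate(divide="ignore"):  # pseudocount 0 -> -inf for unseen
            weights[out_j] = np.log2(freqs / background)
    return ProfileMatrix(name=name, weights=weights, background=background)


def default_profiles(
    pseudocount: float = 0.5,
    calibrate: bool = True,
    n_shuffles: int = 1000,
    length: int = 300,
    seed: int = 17,
) -> dict[str, ProfileMatrix]:
    """The four packaged profiles (MADS, K1, K2, K3), optionally calibrated."""
    out: dict[str, ProfileMatrix] = {}
    for i, name in enumerate(("MADS", "K1", "K2", "K3")):
        prof = build_profile(seed_alignment(name), pseudocount=pseudocount, name=name)
        if calibrate:
            calibrate_evalue(prof, n_shuffles=n_shuffles, length=length, seed=seed + i)
        out[name] = prof
    return out


def encode(seq: str) -> np.ndarray:
    """Integer-encode a protein; X maps to index 20 (scored zero)."""
    seq = seq.upper()
    idx = np.empty(len(seq), dtype=np.intp)
    for i, c in enumerate(seq):
        if c == "X":
            idx[i] = len(AA_ORDER)
        elif c in AA_INDEX:
            idx[i] = AA_INDEX[c]
        else:
            raise ProfileError(f"illegal residue {c!r} at position {i}")
    return idx


def window_scores(profile: ProfileMatrix, seq: str) -> np.ndarray:
    """Score of every length-L window of ``seq`` (empty array if too short)."""
    L = profile.length
    idx = encode(seq)
    if idx.size < L:
        return np.empty(0)
    # extra zero column scores X
    w = np.hstack([profile.weights, np.zeros((L, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return w[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    profile: ProfileMatrix,
    protein: str,
    protein_id: str = "query",
    evalue: float = 1e-3,
    database_size: int = 1,
    min_score: float | None = None,
) -> list[DomainHit]:
    """Significant non-overlapping hits of one profile on one protein.

    Windows are selected greedily by descending score; a window overlapping an
    already-accepted hit is discarded. The cutoff is either an explicit
    ``min_score`` or the calibrated score whose E-value (at ``database_size``)
    falls below ``evalue``.
    """
    scores = window_scores(profile, protein)
    if scores.size == 0:
        return []
    if min_score is None:
        min_score = profile.score_threshold(evalue, database_size)
    L = profile.length
    order = np.argsort(scores, kind="stable")[::-1]
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for i in order:
        s = float(scores[i])
        if s < min_score:
            break
        start, end = int(i), int(i) + L
        if any(start < e and b < end for b, e in taken):
            continue
        taken.append((start, end))
        ev = profile.evalue(s, database_size) if profile.calibrated else float("nan")
        hits.append(
            DomainHit(
                protein_id=protein_id,
                profile_name=profile.name,
                start=start,
                end=end,
                score=s,
                evalue=max(ev, 0.0) if ev == ev else ev,
            )
        )
    return hits


def calibrate_evalue(
    profile: ProfileMatrix, n_shuffles: int = 1000, length: int = 300, seed: int = 17
) -> tuple[float, float]:
    """Fit the Gumbel null of maximal window scores on random background sequences.

    ``n_shuffles`` sequences of ``length`` residues are drawn i.i.d. from the
    profile's background composition; the per-sequence maximal window score is
    fit with a Gumbel (location mu, rate lambda = 1/scale). The profile is
    updated in place and (mu, lambda) returned. Deterministic given ``seed``.
    """
    if n_shuffles < 100:
        raise ProfileError("n_shuffles must be >= 100")
    if length < profile.length:
        raise ProfileError("calibration length shorter than the profile")
    rng = np.random.default_rng(seed)
    L = profile.length
    w = np.hstack([profile.weights, np.zeros((L, 1))])
    draws = rng.choice(len(AA_ORDER), size=(n_shuffles, length), p=profile.background)
    maxima = np.empty(n_shuffles)
    pos = np.arange(L)
    for i in range(n_shuffles):
        windows = np.lib.stride_tricks.sliding_window_view(draws[i], L)
        maxima[i] = w[pos, windows].sum(axis=1).max()
    if np.std(maxima) == 0:
        raise CalibrationError("degenerate (zero-variance) score distribution")
    # Tail-weighted fit: for a Gumbel, log(-log F(x)) is linear in x with
    # slope -lambda. Regressing that transform of the empirical CDF over the
    # upper half of the sample calibrates the significance tail accurately,
    # where a plain maximum-likelihood fit lets the bulk distort the tail.
    mx = np.sort(maxima)
    ecdf = (np.arange(1, n_shuffles + 1) - 0.5) / n_shuffles
    sel = slice(n_shuffles // 2, max(n_shuffles - 5, n_shuffles // 2 + 2))
    slope, intercept = np.polyfit(mx[sel], np.log(-np.log(ecdf[sel])), 1)
    if slope >= 0:
        raise CalibrationError("calibration failed: non-decreasing tail fit")
    lam = -float(slope)
    profile.gumbel_mu = float(intercept) / lam
    profile.gumbel_lambda = lam
    return profile.gumbel_mu, profile.gumbel_lambda


def call_architecture(
    hits: list[DomainHit], exon_count: int, protein_id: str | None = None
) -> ArchitectureCall:
    """Type I/II assignment from domain hits plus gene structure.

    Type II (MIKC) requires a MADS hit with at least two of the K1/K2/K3
    segments downstream of it; Type I requires a MADS hit, no K segments, and
    a gene of at most two exons. A lone K segment, or a multi-exon gene with a
    MADS hit but no K segments, flags the model for reannotation (truncated or
    mis-assembled K domain).
    """
    if protein_id is None:
        protein_id = hits[0].protein_id if hits else "query"
    if hits and any(h.protein_id != protein_id for h in hits):
        raise ProfileError("hits must all belong to one protein")
    mads = [h for h in hits if h.profile_name == "MADS"]
    if not mads:
        return ArchitectureCall(protein_id, "unclassified", 0, False, "no MADS domain")
    best_mads = max(mads, key=lambda h: h.score)
    k_names = {
        h.profile_name
        for h in hits
        if h.profile_name in ("K1", "K2", "K3") and h.start >= best_mads.end
    }
    k_found = len(k_names)
    if k_found >= 2:
        return ArchitectureCall(protein_id, "TypeII", k_found, False)
    if k_found == 1:
        return ArchitectureCall(
            protein_id,
            "unclassified",
            1,
            True,
            f"K domain too short: only {next(iter(k_names))} present",
        )
    if exon_count <= 2:
        return ArchitectureCall(protein_id, "TypeI", 0, False)
    return ArchitectureCall(
        protein_id,
        "unclassified",
        0,
        True,
        f"{exon_count}-exon gene with MADS domain but no K segments",
    )


#: Kyte–Doolittle hydropathy values
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}


def hydropathy_flag(seq: str, window: int = 19, threshold: float = 1.6) -> bool:
    """Heuristic transmembrane ("odd domain") screen.

    True when any 19-residue window has mean Kyte–Doolittle hydropathy above
    the threshold. Flag-only: callers report it, nothing is re-predicted.
    """
    vals = np.array([_KD[c] for c in seq.upper()])
    if vals.size < window:
        return False
    sw = np.lib.stride_tricks.sliding_window_view(vals, window)
    return bool(sw.mean(axis=1).max() > threshold)
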