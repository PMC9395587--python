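"""Activation-microswitch classification.

Rotamer-basin occupancies of toggle-switch chi1 series, modality calls,
nearest-crystal-reference state assignment, ionic-lock/salt-bridge
formed-fraction, and the combined activation fingerprint.

Shipped reference values (crystal structures of the antagonist- and
agonist-bound CB1 receptor): chi1 of the 3.36 residue 182.18° (inactive,
5TGZ) and 280.59° (active, 5XRA); R3.50(CZ)–D6.30(CG) lock distances
4.5 Å / 4.7 Å (5TGZ / 5U09, formed) and 8.8 Å (5XRA, broken).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import DihedralSeries, DistanceSeries

__all__ = [
    "RotamerBasins",
    "RotamerDistribution",
    "ModalityCall",
    "ReferenceStateSet",
    "LockAnalysis",
    "Fingerprint",
    "rotamer_distribution",
    "classify_modality",
    "nearest_reference_state",
    "lock_analysis",
    "activation_fingerprint",
    "circular_mean",
    "CB1_CHI1_REFERENCES",
    "CB1_LOCK_REFERENCES",
    "RULE_VERSION",
]

RULE_VERSION = "1.0"

#: crystal reference chi1 angles for the CB1 3.36 toggle-switch residue
CB1_CHI1_REFERENCES = (("active", 280.59), ("inactive", 182.18))
#: crystal reference lock distances (Å), R3.50(CZ)-D6.30(CG)
CB1_LOCK_REFERENCES = {
    "antagonist-bound 5TGZ": 4.5,
    "antagonist-bound 5U09": 4.7,
    "agonist-bound 5XRA": 8.8,
}

#: default formed-lock threshold: the larger antagonist-bound reference
DEFAULT_LOCK_THRESHOLD = 4.7


@dataclass(frozen=True)
class RotamerBasins:
    """Named circular intervals (degrees) partitioning [0, 360).

    Intervals are half-open ``[lo, hi)``; an interval with ``lo > hi``
    wraps through 360/0.
    """

    intervals: tuple[tuple[str, float, float], ...] = (
        ("gauche-", 0.0, 120.0),
        ("trans", 120.0, 240.0),
        ("gauche+", 240.0, 360.0),
    )

    def __post_init__(self) -> None:
        # verify the intervals partition [0, 360)
        cover = np.zeros(360, dtype=int)
        for _, lo, hi in self.intervals:
            grid = np.arange(360) + 0.5
            if lo <= hi:
                cover += ((grid >= lo) & (grid < hi)).astype(int)
            else:
                cover += ((grid >= lo) | (grid < hi)).astype(int)
        if not np.all(cover == 1):
            raise ValueError("basin intervals must partition [0, 360)")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def assign(self, angles: np.ndarray) -> np.ndarray:
        """Basin index per angle."""
        angles = np.asarray(angles, dtype=float) % 360.0
        out = np.full(angles.shape, -1, dtype=int)
        for k, (_, lo, hi) in enumerate(self.intervals):
            if lo <= hi:
                mask = (angles >= lo) & (angles < hi)
            else:
                mask = (angles >= lo) | (angles < hi)
            out[mask] = k
        return out


DEFAULT_BASINS = RotamerBasins()


@dataclass
class RotamerDistribution:
    """Basin occupancies and circular histogram of one dihedral series."""

    basins: RotamerBasins
    occupancy: dict[str, float]
    histogram: np.ndarray  # counts per bin
    bin_width: float
    n_frames: int
    angles: np.ndarray  # retained for dominant-basin statistics

    def __post_init__(self) -> None:
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {total}, not 1")
        if int(self.histogram.sum()) != self.n_frames:
            raise ValueError("histogram mass must equal n_frames")


@dataclass(frozen=True)
class ModalityCall:
    label: str  # unimodal | bimodal | multimodal | indeterminate
    occupied_basins: tuple[str, ...]
    min_occupancy: float


@dataclass(frozen=True)
class ReferenceStateSet:
    """Named crystal reference angles, e.g. (("inactive", 182.18), ...)."""

    states: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.states]
        if len(set(names)) != len(names):
            raise ValueError("reference state names must be unique")
        for n, a in self.states:
            if not 0 <= a < 360:
                raise ValueError(f"reference angle for {n!r} outside [0, 360)")


@dataclass
class LockAnalysis:
    threshold_formed: float
    formed: np.ndarray  # per-frame boolean
    formed_fraction: float
    references: dict[str, float] = field(default_factory=dict)


@dataclass
class Fingerprint:
    """Per-feature votes and the overall agonist/antagonist-like call."""

    votes: dict[str, str]
    overall: str
    rule_version: str
    thresholds: dict[str, float]
    dominant_state: str | None = None


# ---- operations ------------------------------------------------------------


def rotamer_distribution(
    d: DihedralSeries,
    basins: RotamerBasins = DEFAULT_BASINS,
    bin_width: float = 10.0,
) -> RotamerDistribution:
    """Basin occupancies and a circular histogram of a dihedral series."""
    if d.n_frames == 0:
        raise ValueError("empty dihedral series")
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    assignment = basins.assign(d.angles)
    occupancy = {
        name: float(np.mean(assignment == k)) for k, name in enumerate(basins.names)
    }
    n_bins = int(round(360.0 / bin_width))
    histogram, _ = np.histogram(d.angles, bins=n_bins, range=(0.0, 360.0))
    return RotamerDistribution(
        basins=basins,
        occupancy=occupancy,
        histogram=histogram,
        bin_width=bin_width,
        n_frames=d.n_frames,
        angles=np.asarray(d.angles, dtype=float),
    )


def classify_modality(
    r: RotamerDistribution, min_occupancy: float = 0.10
) -> ModalityCall:
    """unimodal/bimodal/multimodal by counting basins above ``min_occupancy``."""
    occupied = tuple(
        name for name in r.basins.names if r.occupancy[name] >= min_occupancy
    )
    label = {1: "unimodal", 2: "bimodal", 3: "multimodal"}.get(len(occupied))
    if label is None:
        warnings.warn(
            f"no basin reaches occupancy {min_occupancy}; modality indeterminate"
        )
        label = "indeterminate"
    return ModalityCall(label=label, occupied_basins=occupied, min_occupancy=min_occupancy)


def circular_distance(a: float, b: float) -> float:
    """min(|Δ|, 360 − |Δ|) in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def circular_mean(angles: np.ndarray) -> float:
    """Circular mean in degrees, mapped to [0, 360)."""
    rad = np.radians(np.asarray(angles, dtype=float))
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))) % 360.0
    return float(0.0 if mean >= 360.0 else mean)


def nearest_reference_state(angle: float, refs: ReferenceStateSet) -> str:
    """Name of the reference state circularly closest to ``angle``.

    Exact ties go to the lexicographically first state name.
    """
    if not refs.states:
        raise ValueError("empty reference state set")
    best = min(refs.states, key=lambda s: (circular_distance(angle, s[1]), s[0]))
    return best[0]


def dominant_basin_angle(r: RotamerDistribution) -> float:
    """Circular mean of the frames in the highest-occupancy basin."""
    names = r.basins.names
    dominant = max(names, key=lambda n: r.occupancy[n])
    k = names.index(dominant)
    mask = r.basins.assign(r.angles) == k
    if not np.any(mask):
        raise ValueError("dominant basin has no frames")
    return circular_mean(r.angles[mask])


def lock_analysis(
    d: DistanceSeries,
    threshold_formed: float = DEFAULT_LOCK_THRESHOLD,
    refs: dict[str, float] | None = None,
) -> LockAnalysis:
    """Per-frame formed/broken call of a salt bridge and its formed fraction.

    formed(frame) = distance ≤ ``threshold_formed``; reference distances are
    carried along as annotations, never used as thresholds.
    """
    if d.n_frames == 0:
        raise ValueError("empty distance series")
    if threshold_formed <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_formed}")
    formed = d.values <= threshold_formed
    return LockAnalysis(
        threshold_formed=threshold_formed,
        formed=formed,
        formed_fraction=float(np.mean(formed)),
        references=dict(refs) if refs else dict(CB1_LOCK_REFERENCES),
    )


def activation_fingerprint(
    modality: ModalityCall,
    dominant_state: str | None,
    lock: LockAnalysis,
    lock_agonist_below: float = 0.5,
) -> Fingerprint:
    """Combine toggle-switch and lock evidence into an overall call.

    Default rule (version 1.0): toggle vote is agonist-like iff the
    distribution is bimodal/multimodal or the dominant basin sits nearest
    the active crystal reference; lock vote is agonist-like iff
    formed_fraction < ``lock_agonist_below``. Overall = majority of votes,
    ties → indeterminate.
    """
    toggle_agonist = modality.label in ("bimodal", "multimodal") or (
        dominant_state == "active"
    )
    votes = {
        "toggle_switch": "agonist-like" if toggle_agonist else "antagonist-like",
        "ionic_lock": (
            "agonist-like"
            if lock.formed_fraction < lock_agonist_below
            else "antagonist-like"
        ),
    }
    n_ago = sum(1 for v in votes.values() if v == "agonist-like")
    n_ant = sum(1 for v in votes.values() if v == "antagonist-like")
    overall = (
        "agonist-like"
        if n_ago > n_ant
        else "antagonist-like" if n_ant > n_ago else "indeterminate"
    )
    return Fingerprint(
        votes=votes,
        overall=overall,
        rule_version=RULE_VERSION,
        thresholds={
            "min_occupancy": modality.min_occupancy,
            "lock_threshold_formed": lock.threshold_formed,
            "lock_agonist_below": lock_agonist_below,
        },
        dominant_state=dominant_state,
    )
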