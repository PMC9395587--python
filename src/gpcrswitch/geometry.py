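"""Geometric kernels: dihedrals, distances, ring centroids, per-frame series.

Dihedral angles follow the IUPAC sign convention mapped onto [0, 360):
looking from the second to the third atom, a clockwise rotation of the
far bond relative to the near bond is positive. Angles the paper reports
as basins like "around 280°–320°" live naturally on this range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_structures import SeriesTable, Structure

__all__ = [
    "DihedralSeries",
    "DistanceSeries",
    "DegenerateGeometryError",
    "NoChi1Error",
    "dihedral",
    "chi1_series",
    "distance_series",
    "ring_centroid_distance_series",
    "RING_ATOMS",
]

#: built-in aromatic ring atom sets for standard residues
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),  # six-membered ring
    "TRP5": ("CG", "CD1", "CD2", "NE1", "CE2"),  # five-membered ring
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CHI1_ATOMS = ("N", "CA", "CB", "CG")
_NO_CHI1 = {"GLY", "ALA"}
_BOND_GUARD = 3.0  # Å; warn when a "bonded" pair stretches beyond this


class DegenerateGeometryError(ValueError):
    """Coincident or collinear points where a dihedral is undefined."""


class NoChi1Error(ValueError):
    """Residue has no N-CA-CB-CG chi1 (Gly/Ala or missing atoms)."""


@dataclass
class DihedralSeries:
    """Per-frame dihedral (degrees in [0, 360)) of one residue's atom quartet."""

    residue_id: int
    atom_names: tuple[str, str, str, str]
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any((self.angles < 0) | (self.angles >= 360)):
            raise ValueError("angles must lie in [0, 360)")

    @property
    def n_frames(self) -> int:
        return self.angles.size

    def as_table(self, label: str | None = None) -> SeriesTable:
        label = label or f"chi1_res{self.residue_id}"
        return SeriesTable(label=label, unit="degrees", values=self.angles)


@dataclass
class DistanceSeries:
    """Per-frame distance (Å > 0) between two endpoints."""

    endpoint_a: tuple
    endpoint_b: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def as_table(self, label: str | None = None) -> SeriesTable:
        label = label or f"dist_{self.endpoint_a}_{self.endpoint_b}"
        return SeriesTable(label=label, unit="Å", values=self.values)


# ---- kernels ---------------------------------------------------------------


def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Dihedral angle (degrees in [0, 360)) of four points.

    Accepts single points of shape (3,) or stacked frames of shape (n, 3);
    invariant under rigid-body rotation/translation of all four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    scalar = p1.ndim == 1
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for name, b in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.any(np.linalg.norm(np.atleast_2d(b), axis=1) < 1e-10):
            raise DegenerateGeometryError(f"consecutive points {name} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(np.atleast_2d(n1), axis=1) < 1e-10) or np.any(
        np.linalg.norm(np.atleast_2d(n2), axis=1) < 1e-10
    ):
        raise DegenerateGeometryError("three consecutive points are collinear")
    u_b2 = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    y = np.sum(np.cross(n1, n2) * u_b2, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    # guard against 360.0 from floating-point wrap of tiny negative angles
    ang = np.where(ang >= 360.0, 0.0, ang)
    return float(ang) if scalar else ang


def chi1_series(s: Structure, residue_id: int) -> DihedralSeries:
    """chi1 (N-CA-CB-CG) dihedral of one residue over all frames."""
    resname = None
    for a in s.atoms:
        if a.residue_id == residue_id:
            resname = a.residue_name
            break
    if resname is None:
        raise KeyError(f"residue {residue_id} not found in structure")
    if resname in _NO_CHI1:
        raise NoChi1Error(f"residue {residue_id} ({resname}) has no chi1")
    idx = []
    for name in CHI1_ATOMS:
        try:
            idx.append(s.atom_index(residue_id, name))
        except KeyError:
            raise NoChi1Error(
                f"residue {residue_id} ({resname}) lacks atom {name} needed for chi1"
            ) from None
    pts = [s.coords[:, i, :] for i in idx]
    _bond_guard(pts, residue_id)
    angles = dihedral(*pts)
    return DihedralSeries(
        residue_id=residue_id, atom_names=CHI1_ATOMS, angles=np.atleast_1d(angles)
    )


def _bond_guard(pts: list[np.ndarray], residue_id: int) -> None:
    for a, b in zip(pts, pts[1:]):
        if np.any(np.linalg.norm(a - b, axis=-1) > _BOND_GUARD):
            warnings.warn(
                f"residue {residue_id}: bonded-atom pair exceeds {_BOND_GUARD} Å "
                "in some frame; coordinates may not be whole/imaged"
            )
            return


def distance_series(
    s: Structure,
    a: tuple[int, str],
    b: tuple[int, str],
) -> DistanceSeries:
    """Euclidean distance between two named atoms per frame."""
    ia = s.atom_index(*a)
    ib = s.atom_index(*b)
    values = np.linalg.norm(s.coords[:, ia, :] - s.coords[:, ib, :], axis=1)
    return DistanceSeries(endpoint_a=a, endpoint_b=b, values=values)


def _centroid(s: Structure, indices: list[int]) -> np.ndarray:
    if not indices:
        raise ValueError("empty atom set")
    return s.coords[:, indices, :].mean(axis=1)


def ring_atom_indices(s: Structure, residue_id: int, ring: str | None = None) -> list[int]:
    """Indices of a standard residue's aromatic ring atoms.

    ``ring`` overrides the residue-name lookup (e.g. "TRP5" for the
    five-membered tryptophan ring).
    """
    resname = ring
    if resname is None:
        for a in s.atoms:
            if a.residue_id == residue_id:
                resname = a.residue_name
                break
    if resname not in RING_ATOMS:
        raise ValueError(f"no built-in ring definition for {resname!r}")
    return [s.atom_index(residue_id, n) for n in RING_ATOMS[resname]]


def ring_centroid_distance_series(
    s: Structure,
    ring_atoms: list[int],
    target: tuple[int, str] | list[int],
) -> DistanceSeries:
    """Distance between the unweighted centroid of ``ring_atoms`` and a
    target atom or the centroid of a second atom set, per frame."""
    ca = _centroid(s, list(ring_atoms))
    if isinstance(target, tuple):
        cb = s.coords[:, s.atom_index(*target), :]
        endpoint_b = target
    else:
        cb = _centroid(s, list(target))
        endpoint_b = ("centroid", tuple(target))
    values = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(
        endpoint_a=("centroid", tuple(ring_atoms)), endpoint_b=endpoint_b, values=values
    )
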