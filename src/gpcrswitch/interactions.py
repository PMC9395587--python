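"""Ligand-centric analyses: binding-site residue delineation and
bridging-water polar contacts.

All distance criteria are heavy-atom only; "polar interaction" is a
distance-only proxy (no angle criterion), matching the granularity at
which binding-site residues are reported by typical MD contact analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_structures import Structure, WATER_RESNAMES

__all__ = [
    "BindingSiteReport",
    "binding_site_residues",
    "bridging_water_series",
]


@dataclass
class BindingSiteReport:
    """Per-residue ligand contact fractions and the thresholded residue list."""

    ligand_residue_ids: list[int]
    cutoff: float
    min_fraction: float
    contact_fraction: dict[int, float]  # every residue with fraction > 0
    residues: list[int]  # those passing min_fraction

    def __post_init__(self) -> None:
        for r in self.residues:
            if self.contact_fraction.get(r, 0.0) < self.min_fraction:
                raise ValueError(f"residue {r} listed but below min_fraction")


def binding_site_residues(
    s: Structure,
    ligand: list[int] | dict,
    cutoff: float = 4.5,
    min_fraction: float = 0.5,
) -> BindingSiteReport:
    """Residues whose heavy atoms come within ``cutoff`` of any ligand heavy
    atom in at least ``min_fraction`` of frames.

    ``ligand`` is either a list of atom indices or a selection dict
    (e.g. ``{"residue_name": "CBD"}``).
    """
    if isinstance(ligand, dict):
        lig_idx = s.select(
            residue_name=ligand.get("residue_name"),
            element=ligand.get("element"),
            name=ligand.get("name"),
            heavy_only=True,
        )
    else:
        lig_idx = [i for i in ligand if s.atoms[i].is_heavy]
    if not lig_idx:
        raise ValueError("ligand selection matched no heavy atoms")
    lig_resids = {s.atoms[i].residue_id for i in lig_idx}
    lig_xyz = s.coords[:, lig_idx, :]  # (F, L, 3)

    resnames = {at.residue_id: at.residue_name for at in s.atoms}
    fractions: dict[int, float] = {}
    for r in s.residue_ids():
        if r in lig_resids or resnames[r] in WATER_RESNAMES:
            continue
        heavy = s.heavy_indices(r)
        if not heavy:
            continue
        res_xyz = s.coords[:, heavy, :]
        d = np.linalg.norm(res_xyz[:, :, None, :] - lig_xyz[:, None, :, :], axis=-1)
        per_frame = d.reshape(d.shape[0], -1).min(axis=1) <= cutoff
        frac = float(per_frame.mean())
        if frac > 0:
            fractions[r] = frac
    residues = sorted(r for r, f in fractions.items() if f >= min_fraction)
    return BindingSiteReport(
        ligand_residue_ids=sorted(lig_resids),
        cutoff=cutoff,
        min_fraction=min_fraction,
        contact_fraction=fractions,
        residues=residues,
    )


def bridging_water_series(
    s: Structure,
    a: tuple[int, str],
    b: tuple[int, str],
    cutoff: float = 3.5,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> np.ndarray:
    """Per-frame boolean: some water oxygen is within ``cutoff`` of both
    endpoints simultaneously."""
    ia = s.atom_index(*a)
    ib = s.atom_index(*b)
    w_idx = [
        i
        for i, at in enumerate(s.atoms)
        if at.residue_name in water_resnames and at.element.upper() == "O"
    ]
    if not w_idx:
        return np.zeros(s.n_frames, dtype=bool)
    w_xyz = s.coords[:, w_idx, :]  # (F, W, 3)
    da = np.linalg.norm(w_xyz - s.coords[:, ia, None, :], axis=-1)
    db = np.linalg.norm(w_xyz - s.coords[:, ib, None, :], axis=-1)
    return np.any((da <= cutoff) & (db <= cutoff), axis=1)
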