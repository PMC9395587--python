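"""Residue–ion contact maps, persistence, and co-contact site detection.

A residue is in contact with an ion in a frame iff the minimum distance
from any of the residue's heavy atoms to the ion is ≤ cutoff (inclusive;
default 4.0 Å). Residues are grouped into candidate ion-binding sites by
single-linkage over the "contacts the same ion in at least one common
frame" relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io_structures import Structure

__all__ = [
    "IonContactMap",
    "IonSite",
    "ion_contact_map",
    "contact_persistence",
    "detect_sites",
    "episodes",
    "write_contact_map",
]


@dataclass
class IonContactMap:
    """Boolean occupancy per (residue, ion, frame)."""

    residues: list[int]
    ions: list[int]  # atom serials of the matched ion atoms
    occupancy: np.ndarray  # shape (n_residues, n_ions, n_frames), bool
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        expected = (len(self.residues), len(self.ions))
        if self.occupancy.shape[:2] != expected:
            raise ValueError("occupancy shape does not match residues × ions")

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[2]

    def any_ion(self) -> np.ndarray:
        """Per-(residue, frame) contact with any ion."""
        return self.occupancy.any(axis=1)


@dataclass
class IonSite:
    """A co-contacting residue group with persistence and episode summaries."""

    residues: list[int]
    ions: list[int]
    persistence: dict[int, float]  # per residue, fraction of frames
    site_persistence: float  # fraction of frames any member touches a site ion
    episode_count: dict[int, int]
    episode_lengths: dict[int, list[int]]


def ion_contact_map(
    s: Structure,
    ion_selection: dict | None = None,
    residues: list[int] | None = None,
    cutoff: float = 4.0,
) -> IonContactMap:
    """Contact map of protein residues against matched ion atoms.

    ``ion_selection`` filters atoms by ``element`` and/or ``name``
    (default: element Na). ``residues`` defaults to all non-water residues
    that are not themselves matched ions. Contact uses residue heavy atoms
    only and an inclusive cutoff ("4 Å or less").
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sel = dict(ion_selection or {"element": "NA"})
    ion_idx = s.select(
        element=sel.get("element"),
        name=sel.get("name"),
        residue_name=sel.get("residue_name"),
    )
    if not ion_idx:
        raise ValueError(f"no ion atoms matched selection {sel!r}")
    ion_resids = {s.atoms[i].residue_id for i in ion_idx}
    if residues is None:
        residues = [r for r in s.residue_ids(protein_only=True) if r not in ion_resids]
    heavy = {r: s.heavy_indices(r) for r in residues}
    missing = [r for r, idx in heavy.items() if not idx]
    if missing:
        raise KeyError(f"residues without heavy atoms: {missing}")

    n_frames = s.n_frames
    occupancy = np.zeros((len(residues), len(ion_idx), n_frames), dtype=bool)
    ion_xyz = s.coords[:, ion_idx, :]  # (F, I, 3)
    for ri, r in enumerate(residues):
        res_xyz = s.coords[:, heavy[r], :]  # (F, A, 3)
        # (F, A, I) pairwise distances, min over residue atoms
        d = np.linalg.norm(res_xyz[:, :, None, :] - ion_xyz[:, None, :, :], axis=-1)
        occupancy[ri] = (d.min(axis=1) <= cutoff).T
    return IonContactMap(
        residues=list(residues),
        ions=[s.atoms[i].serial for i in ion_idx],
        occupancy=occupancy,
        cutoff=cutoff,
    )


def contact_persistence(m: IonContactMap) -> dict[int, float]:
    """Per-residue fraction of frames in contact with any ion."""
    if m.n_frames == 0:
        raise ValueError("empty contact map")
    any_ion = m.any_ion()
    return {r: float(any_ion[ri].mean()) for ri, r in enumerate(m.residues)}


def episodes(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of consecutive True frames."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return (stops - starts).tolist()


def detect_sites(
    m: IonContactMap,
    min_residues: int = 2,
    min_persistence: float = 0.25,
) -> list[IonSite]:
    """Group residues into candidate ion-binding sites.

    Two residues are linked iff they contact the same ion in ≥1 common
    frame; connected components with ≥ ``min_residues`` members and
    site-level persistence ≥ ``min_persistence`` are reported. Output is
    invariant to residue ordering and ion relabelling.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(m.residues)))
    for ii in range(len(m.ions)):
        occ = m.occupancy[:, ii, :]  # (R, F)
        touching = np.flatnonzero(occ.any(axis=1))
        for a_pos, ra in enumerate(touching):
            for rb in touching[a_pos + 1 :]:
                if np.any(occ[ra] & occ[rb]):
                    g.add_edge(int(ra), int(rb))
    sites = []
    for comp in nx.connected_components(g):
        # order by residue id so output is invariant to input ordering
        members = sorted(comp, key=lambda r: m.residues[r])
        if len(members) < min_residues:
            continue
        occ = m.occupancy[members]  # (R', I, F)
        site_ions = [
            m.ions[ii] for ii in range(len(m.ions)) if occ[:, ii, :].any()
        ]
        if not site_ions:
            continue
        any_ion = occ.any(axis=1)  # (R', F)
        site_frames = any_ion.any(axis=0)
        site_persistence = float(site_frames.mean())
        if site_persistence < min_persistence:
            continue
        persistence = {
            m.residues[r]: float(any_ion[k].mean()) for k, r in enumerate(members)
        }
        ep_lengths = {
            m.residues[r]: episodes(any_ion[k]) for k, r in enumerate(members)
        }
        sites.append(
            IonSite(
                residues=[m.residues[r] for r in members],
                ions=site_ions,
                persistence=persistence,
                site_persistence=site_persistence,
                episode_count={r: len(v) for r, v in ep_lengths.items()},
                episode_lengths=ep_lengths,
            )
        )
    sites.sort(key=lambda s: s.residues)
    return sites


def write_contact_map(m: IonContactMap, path: str | Path) -> None:
    """TSV matrix: rows residues, columns frames, 1 = contact with any ion."""
    any_ion = m.any_ion().astype(int)
    lines = ["residue\t" + "\t".join(str(f) for f in range(m.n_frames))]
    for ri, r in enumerate(m.residues):
        lines.append(f"{r}\t" + "\t".join(str(v) for v in any_ion[ri]))
    Path(path).write_text("\n".join(lines) + "\n")
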