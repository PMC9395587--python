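"""Synthetic trajectories with ground-truth labels.

Generates the statistical structure the analysis layer assumes — hidden
rotamer-state switching (Markov chain + von Mises emissions), two-state
formed/broken salt-bridge dynamics, episodic ion binding, and static
ligand contact geometry — and embeds it into multi-model PDB fixtures via
exact internal-coordinate (NeRF) construction, so that the geometry module
recovers every generated value to numerical tolerance.

Trajectory realism is explicitly not a goal: fixtures are minimal
pseudo-residue constructs sufficient to exercise every analysis contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_structures import Atom, Structure, write_structure
from .numbering import HelixAnnotation, write_annotation

__all__ = [
    "RotamerSwitchConfig",
    "LockSwitchConfig",
    "IonEpisodeConfig",
    "LigandContactConfig",
    "GroundTruth",
    "simulate_markov_chain",
    "stationary_distribution",
    "simulate_rotamer_series",
    "simulate_lock_series",
    "simulate_ion_episodes",
    "nerf_place",
    "embed_features",
    "make_benchmark_suite",
    "PANELS",
]

# fixed internal coordinates of the embedded N-CA-CB-CG quartet
_BOND_N_CA = 1.46
_BOND_CA_CB = 1.53
_BOND_CB_CG = 1.53
_ANGLE = 110.0  # degrees, both backbone-side angles


def _check_stochastic(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return t


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    t = _check_stochastic(t)
    vals, vecs = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_markov_chain(
    t: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """State sequence of length ``n_frames``; initial state drawn from the
    stationary distribution."""
    t = _check_stochastic(t)
    pi = stationary_distribution(t)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    for i in range(1, n_frames):
        states[i] = rng.choice(t.shape[0], p=t[states[i - 1]])
    return states


@dataclass(frozen=True)
class RotamerSwitchConfig:
    """Hidden-state chi1 dynamics: Markov switching + von Mises emission."""

    centers: tuple[float, ...]  # degrees, one per state
    kappas: tuple[float, ...]  # von Mises concentration per state
    transition: tuple[tuple[float, ...], ...]
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.kappas):
            raise ValueError("centers and kappas must align")
        if any(k <= 0 for k in self.kappas):
            raise ValueError("kappa must be positive")
        _check_stochastic(np.array(self.transition))


@dataclass(frozen=True)
class LockSwitchConfig:
    """Two-state formed/broken distance dynamics with Gaussian noise."""

    mean_formed: float = 4.5
    mean_broken: float = 9.5
    noise_sd: float = 0.3
    transition: tuple[tuple[float, ...], ...] = ((0.95, 0.05), (0.05, 0.95))
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_formed <= 0 or self.mean_broken <= 0:
            raise ValueError("mean distances must be positive")
        _check_stochastic(np.array(self.transition))


@dataclass(frozen=True)
class IonEpisodeConfig:
    """Episodic ion binding to a cluster of site residues.

    Dwell times in the bound/unbound states are geometric; bound frames
    place the ion within ``bound_distance`` of every site residue,
    unbound frames at ``unbound_distance``.
    """

    n_site_residues: int = 3
    p_leave_bound: float = 0.05
    p_enter_bound: float = 0.05
    bound_distance: float = 2.8
    unbound_distance: float = 30.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_leave_bound <= 1 or not 0 < self.p_enter_bound <= 1:
            raise ValueError("dwell parameters must be in (0, 1]")
        if self.bound_distance >= self.unbound_distance:
            raise ValueError("bound range must lie strictly below unbound range")


@dataclass(frozen=True)
class LigandContactConfig:
    """A static pseudo-ligand at fixed distance from its contact residues."""

    resname: str = "CBD"
    contact_distance: float = 3.5
    n_contact_residues: int = 3


@dataclass
class GroundTruth:
    """Per-frame hidden labels and realized summaries of one feature."""

    kind: str
    states: np.ndarray
    values: np.ndarray
    realized_occupancy: dict[str, float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "kind": self.kind,
            "states": self.states.astype(int).tolist(),
            "values": [round(float(v), 6) for v in self.values],
            "realized_occupancy": {
                k: round(float(v), 6) for k, v in self.realized_occupancy.items()
            },
        }


def simulate_rotamer_series(
    c: RotamerSwitchConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Angles (degrees in [0, 360)) plus ground truth for one chi1 feature."""
    rng = rng if rng is not None else np.random.default_rng(c.seed)
    states = simulate_markov_chain(np.array(c.transition), c.n_frames, rng)
    mus = np.radians(np.asarray(c.centers))[states]
    kappas = np.asarray(c.kappas)[states]
    angles = np.degrees(rng.vonmises(mus, kappas)) % 360.0
    angles = np.where(angles >= 360.0, 0.0, angles)
    occ = {
        f"state_{k}": float(np.mean(states == k)) for k in range(len(c.centers))
    }
    return angles, GroundTruth(
        kind="rotamer", states=states, values=angles, realized_occupancy=occ
    )


def simulate_lock_series(
    c: LockSwitchConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Distances (Å) plus ground truth; state 0 = formed, 1 = broken."""
    rng = rng if rng is not None else np.random.default_rng(c.seed)
    states = simulate_markov_chain(np.array(c.transition), c.n_frames, rng)
    means = np.array([c.mean_formed, c.mean_broken])[states]
    values = means + rng.normal(0.0, c.noise_sd, size=c.n_frames)
    values = np.clip(values, 0.5, None)  # distances stay physical
    occ = {
        "formed": float(np.mean(states == 0)),
        "broken": float(np.mean(states == 1)),
    }
    return values, GroundTruth(
        kind="lock", states=states, values=values, realized_occupancy=occ
    )


def simulate_ion_episodes(
    c: IonEpisodeConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Per-frame bound flag (1 = bound) for the episodic ion feature."""
    rng = rng if rng is not None else np.random.default_rng(c.seed)
    t = np.array(
        [
            [1 - c.p_enter_bound, c.p_enter_bound],  # state 0 = unbound
            [c.p_leave_bound, 1 - c.p_leave_bound],  # state 1 = bound
        ]
    )
    states = simulate_markov_chain(t, c.n_frames, rng)
    occ = {"bound": float(np.mean(states == 1))}
    return states, GroundTruth(
        kind="ion",
        states=states,
        values=states.astype(float),
        realized_occupancy=occ,
    )


# ---- geometric embedding ---------------------------------------------------


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom D from A, B, C with given C–D bond length, B–C–D angle and
    A-B-C-D torsion (degrees), natural-extension-reference-frame style."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _quartet_coords(chi: float, origin: np.ndarray) -> np.ndarray:
    """N, CA, CB, CG coordinates with the requested chi1 torsion."""
    n_at = origin + np.array([0.0, 0.0, 0.0])
    ca = origin + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE)
    cb = ca + _BOND_CA_CB * np.array([-math.cos(ang), math.sin(ang), 0.0])
    cg = nerf_place(n_at, ca, cb, _BOND_CB_CG, _ANGLE, chi)
    return np.stack([n_at, ca, cb, cg])


@dataclass(frozen=True)
class RotamerFeature:
    residue_id: int
    residue_name: str  # PHE / TRP / TYR ... (must have a CG)
    series: np.ndarray  # chi1 per frame, degrees


@dataclass(frozen=True)
class LockFeature:
    residue_a: tuple[int, str, str]  # (residue_id, residue_name, atom_name)
    residue_b: tuple[int, str, str]
    series: np.ndarray  # distance per frame, Å


@dataclass(frozen=True)
class IonFeature:
    site_residue_ids: tuple[int, ...]
    bound: np.ndarray  # per-frame 0/1
    config: IonEpisodeConfig


@dataclass(frozen=True)
class LigandFeature:
    residue_id: int
    contact_residue_ids: tuple[int, ...]
    config: LigandContactConfig


def embed_features(
    rotamers: list[RotamerFeature],
    locks: list[LockFeature] | None = None,
    ion: IonFeature | None = None,
    ligand: LigandFeature | None = None,
    chain: str = "A",
) -> Structure:
    """Realize features as a multi-model pseudo-structure.

    Each rotamer becomes an N-CA-CB-CG quartet (NeRF construction, exact
    torsions); each lock endpoint a pseudo-residue whose named side-chain
    atom and CA are co-located, with the pair separated by the generated
    distance; ion features place site-residue atoms in a tight cluster and
    a sodium atom inside/outside the cutoff per frame; a ligand feature
    places contact-residue atoms at the configured distance from a static
    ligand atom. Feature blocks sit 25 Å apart so they cannot interact.
    """
    locks = locks or []
    n_frames_set = {len(r.series) for r in rotamers} | {len(l.series) for l in locks}
    if ion is not None:
        n_frames_set.add(len(ion.bound))
    if len(n_frames_set) != 1:
        raise ValueError(f"features disagree on frame count: {sorted(n_frames_set)}")
    n_frames = n_frames_set.pop()

    atoms: list[Atom] = []
    coords_parts: list[np.ndarray] = []  # each (F, A_i, 3)
    serial = 0
    block = 0

    def block_origin() -> np.ndarray:
        nonlocal block
        origin = np.array([25.0 * block, 0.0, 0.0])
        block += 1
        return origin

    def add_atom(name: str, element: str, resname: str, resid: int) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_id=resid,
                chain=chain,
            )
        )

    for feat in rotamers:
        origin = block_origin()
        quartets = np.stack([_quartet_coords(chi, origin) for chi in feat.series])
        for name in ("N", "CA", "CB", "CG"):
            add_atom(name, name[0], feat.residue_name, feat.residue_id)
        coords_parts.append(quartets)

    for feat in locks:
        origin = block_origin()
        rid_a, rn_a, an_a = feat.residue_a
        rid_b, rn_b, an_b = feat.residue_b
        xyz = np.zeros((n_frames, 4, 3))
        xyz[:, 0] = origin
        xyz[:, 1] = origin
        xyz[:, 2] = origin + np.array([1.0, 0.0, 0.0]) * feat.series[:, None]
        xyz[:, 3] = xyz[:, 2]
        add_atom("CA", "C", rn_a, rid_a)
        add_atom(an_a, an_a[0], rn_a, rid_a)
        add_atom("CA", "C", rn_b, rid_b)
        add_atom(an_b, an_b[0], rn_b, rid_b)
        coords_parts.append(xyz)

    if ion is not None:
        origin = block_origin()
        k = len(ion.site_residue_ids)
        # site residue atoms on a small circle (radius 1.6 Å) around origin
        site_pos = np.array(
            [
                origin
                + 1.6
                * np.array(
                    [math.cos(2 * math.pi * j / k), math.sin(2 * math.pi * j / k), 0.0]
                )
                for j in range(k)
            ]
        )
        xyz = np.zeros((n_frames, k + 1, 3))
        xyz[:, :k] = site_pos
        bound_pos = origin + np.array([0.0, 0.0, ion.config.bound_distance - 1.6])
        # keep the bound ion within bound_distance of every site atom
        unbound_pos = origin + np.array([0.0, 0.0, ion.config.unbound_distance])
        xyz[:, k] = np.where(
            ion.bound[:, None].astype(bool), bound_pos, unbound_pos
        )
        for rid in ion.site_residue_ids:
            add_atom("OD1", "O", "ASP", rid)
        add_atom("NA", "NA", "SOD", max(ion.site_residue_ids) + 500)
        coords_parts.append(xyz)

    if ligand is not None:
        origin = block_origin()
        k = len(ligand.contact_residue_ids)
        xyz = np.zeros((n_frames, k + 1, 3))
        for j in range(k):
            direction = np.array(
                [math.cos(2 * math.pi * j / k), math.sin(2 * math.pi * j / k), 0.0]
            )
            xyz[:, j] = origin + ligand.config.contact_distance * direction
        xyz[:, k] = origin
        for rid in ligand.contact_residue_ids:
            add_atom("CB", "C", "ALA", rid)
        add_atom("C1", "C", ligand.config.resname, ligand.residue_id)
        coords_parts.append(xyz)

    coords = np.concatenate(coords_parts, axis=1)
    return Structure(atoms=atoms, coords=coords)


# ---- benchmark panels ------------------------------------------------------

#: crystal-reference chi1 modes (degrees) for the CB1 3.36 position
_INACTIVE_CHI1 = 182.18
_ACTIVE_CHI1 = 280.59

PANELS = (
    "cb1_agonist_like",
    "cb1_antagonist_like",
    "gpr55_agonist_like",
    "gpr55_antagonist_like",
)

# pseudo-receptor annotations reusing the residue ids the paper prints
_CB1_RAT_ANNOTATION = [
    HelixAnnotation(1, 112, 145, 135),
    HelixAnnotation(2, 150, 179, 164),
    HelixAnnotation(3, 186, 221, 215),
    HelixAnnotation(4, 230, 258, 256),
    HelixAnnotation(5, 270, 310, 287),
    HelixAnnotation(6, 331, 368, 359),
    HelixAnnotation(7, 372, 399, 395),
]
_GPR55_RAT_ANNOTATION = [
    HelixAnnotation(1, 8, 36, 32),
    HelixAnnotation(2, 55, 80, 69),
    HelixAnnotation(3, 90, 125, 119),
    HelixAnnotation(4, 135, 160, 150),
    HelixAnnotation(5, 172, 205, 186),
    HelixAnnotation(6, 213, 250, 241),
    HelixAnnotation(7, 258, 298, 285),
]


def _panel_spec(panel: str, n_frames: int, seed: int) -> dict:
    agonist = panel.endswith("agonist_like") and not panel.endswith(
        "antagonist_like"
    )
    # switching fast enough that 400-frame fixtures recover both basins
    bimodal_t = ((0.9, 0.1), (0.1, 0.9))
    unimodal_t = ((1.0,),)
    if panel.startswith("cb1"):
        toggles = [(201, "PHE"), (357, "TRP")]
        lock = ((215, "ARG", "CZ"), (339, "ASP", "CG"))
        annotation = _CB1_RAT_ANNOTATION
        ion_site = (267, 274, 367)
    elif panel.startswith("gpr55"):
        toggles = [(239, "PHE"), (106, "TYR"), (235, "PHE")]
        lock = ((119, "ARG", "CZ"), (294, "GLU", "CD"))
        annotation = _GPR55_RAT_ANNOTATION
        ion_site = None
    else:
        raise ValueError(f"unknown panel {panel!r}")
    if agonist:
        rot_cfg = RotamerSwitchConfig(
            centers=(_INACTIVE_CHI1, _ACTIVE_CHI1),
            kappas=(25.0, 25.0),
            transition=bimodal_t,
            n_frames=n_frames,
            seed=seed,
        )
        lock_cfg = LockSwitchConfig(
            mean_formed=4.5,
            mean_broken=9.5,
            transition=((0.1, 0.9), (0.01, 0.99)),  # lock mostly broken
            n_frames=n_frames,
            seed=seed,
        )
    else:
        rot_cfg = RotamerSwitchConfig(
            centers=(_INACTIVE_CHI1,),
            kappas=(25.0,),
            transition=unimodal_t,
            n_frames=n_frames,
            seed=seed,
        )
        lock_cfg = LockSwitchConfig(
            mean_formed=4.5,
            mean_broken=9.5,
            transition=((0.99, 0.01), (0.9, 0.1)),  # lock mostly formed
            n_frames=n_frames,
            seed=seed,
        )
    return {
        "label": "agonist-like" if agonist else "antagonist-like",
        "toggles": toggles,
        "lock": lock,
        "annotation": annotation,
        "ion_site": ion_site,
        "rotamer_config": rot_cfg,
        "lock_config": lock_cfg,
    }


def make_benchmark_suite(
    panel: str, seed: int, out_dir: str | Path, n_frames: int = 1000
) -> dict:
    """Write a labelled benchmark fixture: multi-model PDB + helix-anchor
    annotation TSV + ground-truth manifest JSON. Returns the manifest.

    Identical (panel, seed, n_frames) yield byte-identical files.
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; choose from {PANELS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = _panel_spec(panel, n_frames, seed)
    rng = np.random.default_rng(seed)

    rot_feats, rot_truth = [], {}
    for rid, resname in spec["toggles"]:
        angles, truth = simulate_rotamer_series(spec["rotamer_config"], rng)
        rot_feats.append(
            RotamerFeature(residue_id=rid, residue_name=resname, series=angles)
        )
        rot_truth[str(rid)] = truth.to_jsonable()

    lock_values, lock_truth = simulate_lock_series(spec["lock_config"], rng)
    (rid_a, rn_a, an_a), (rid_b, rn_b, an_b) = spec["lock"]
    lock_feat = LockFeature(
        residue_a=(rid_a, rn_a, an_a),
        residue_b=(rid_b, rn_b, an_b),
        series=lock_values,
    )

    ion_feat = None
    ion_truth = None
    if spec["ion_site"] is not None:
        ion_cfg = IonEpisodeConfig(
            n_site_residues=len(spec["ion_site"]), n_frames=n_frames, seed=seed
        )
        bound, truth = simulate_ion_episodes(ion_cfg, rng)
        ion_feat = IonFeature(
            site_residue_ids=tuple(spec["ion_site"]), bound=bound, config=ion_cfg
        )
        ion_truth = truth.to_jsonable()

    structure = embed_features(rot_feats, [lock_feat], ion_feat)
    pdb_path = out_dir / f"{panel}.pdb"
    write_structure(structure, pdb_path)
    ann_path = out_dir / f"{panel}_annotation.tsv"
    write_annotation(spec["annotation"], ann_path)

    manifest = {
        "panel": panel,
        "expected_call": spec["label"],
        "seed": seed,
        "n_frames": n_frames,
        "trajectory": pdb_path.name,
        "annotation": ann_path.name,
        "toggle_residues": [rid for rid, _ in spec["toggles"]],
        "lock": {
            "residue_a": list(spec["lock"][0]),
            "residue_b": list(spec["lock"][1]),
        },
        "ion_site_residues": list(spec["ion_site"]) if spec["ion_site"] else None,
        "ground_truth": {
            "rotamers": rot_truth,
            "lock": lock_truth.to_jsonable(),
            "ion": ion_truth,
        },
    }
    with open(out_dir / f"{panel}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
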