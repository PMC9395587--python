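"""Structure/trajectory I/O and the shared in-memory data model.

The required trajectory dialect is multi-model PDB (``MODEL``/``ENDMDL``
blocks); binary formats are an optional adapter behind the same
:class:`Structure` contract (see :func:`read_trajectory`).

Conventions used throughout the package: coordinates in Å, times in ns,
0-based frame indices. Hydrogens are retained on read but excluded by any
"heavy atom" selector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SeriesTable",
    "PDBParseError",
    "InconsistentTrajectoryError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_series",
    "read_series",
]

#: residue names treated as water by default selectors
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL"})


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; message names the line."""


class InconsistentTrajectoryError(ValueError):
    """Raised when MODEL blocks disagree on atom count or identity."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology shared by all frames."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Structure:
    """An ordered atom list plus one or more coordinate frames.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å. ``frame_times``
    is optional (ns) and must be strictly increasing when present.
    """

    atoms: list[Atom]
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise InconsistentTrajectoryError(
                f"{self.coords.shape[1]} coordinate triples per frame "
                f"for {len(self.atoms)} atoms"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times must have one entry per frame")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # ---- selection helpers -------------------------------------------------

    def atom_index(self, residue_id: int, atom_name: str, chain: str | None = None) -> int:
        """Index of the named atom, or raise ``KeyError`` naming it."""
        for i, a in enumerate(self.atoms):
            if (
                a.residue_id == residue_id
                and a.name == atom_name
                and (chain is None or a.chain == chain)
            ):
                return i
        raise KeyError(f"atom {atom_name!r} of residue {residue_id} not found")

    def residue_ids(self, protein_only: bool = False) -> list[int]:
        """Distinct residue ids in atom order (optionally excluding water)."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if protein_only and a.residue_name in WATER_RESNAMES:
                continue
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def heavy_indices(self, residue_id: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_id == residue_id and a.is_heavy
        ]

    def chain_subset(self, chain: str) -> "Structure":
        """New Structure containing only atoms of one chain."""
        idx = [i for i, a in enumerate(self.atoms) if a.chain == chain]
        if not idx:
            raise KeyError(f"chain {chain!r} not found")
        return Structure(
            atoms=[self.atoms[i] for i in idx],
            coords=self.coords[:, idx, :],
            frame_times=self.frame_times,
        )

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select(
        self,
        residue_name: str | None = None,
        element: str | None = None,
        name: str | None = None,
        heavy_only: bool = False,
    ) -> list[int]:
        """Indices of atoms matching all given filters."""
        out = []
        for i, a in enumerate(self.atoms):
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if element is not None and a.element.upper() != element.upper():
                continue
            if name is not None and a.name != name:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(i)
        return out


@dataclass
class SeriesTable:
    """A per-frame scalar series with a fixed unit ("Å" or "degrees")."""

    label: str
    unit: str
    values: np.ndarray
    times: np.ndarray | None = None

    ALLOWED_UNITS = ("Å", "degrees")

    def __post_init__(self) -> None:
        if self.unit not in self.ALLOWED_UNITS:
            raise ValueError(
                f"unit must be one of {self.ALLOWED_UNITS}, got {self.unit!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D (one row per frame)")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.values.shape:
                raise ValueError("times must align with values")

    def __len__(self) -> int:
        return self.values.size


# ---- PDB parsing -----------------------------------------------------------

_COORD_RECORDS = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int):
    """Parse one ATOM/HETATM record (fixed columns, PDB v3)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed {line[:6].strip()} record at line {lineno}: {exc}"
        ) from exc
    if not element:
        element = _guess_element(name)
    return serial, name, altloc, resname, chain, resid, (x, y, z), occupancy, element


def _guess_element(atom_name: str) -> str:
    # PDB convention: element is the first alphabetic character of the name,
    # except two-letter ions spelled in full (NA, CL, MG, ...).
    stripped = atom_name.strip()
    if stripped.upper() in {"NA", "CL", "MG", "ZN", "CA2", "K", "FE", "MN", "BR"}:
        return stripped.upper().rstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read a single- or multi-model PDB file into a :class:`Structure`.

    MODEL/ENDMDL blocks define frames; a file without them yields one frame.
    Alternate locations are resolved to the highest occupancy (tie → first
    encountered). Atom order must be identical across frames.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    frames: list[list] = []
    current: list | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                if current:
                    frames.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                current = None
            elif rec in _COORD_RECORDS:
                if current is None:
                    current = []
                current.append(_parse_atom_line(line, lineno))
    if current:
        frames.append(current)
    if not frames:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")

    frames = [_resolve_altlocs(f) for f in frames]

    ref = frames[0]
    atoms = [
        Atom(serial=s, name=n, element=el, residue_name=rn, residue_id=ri, chain=ch)
        for (s, n, _, rn, ch, ri, _, _, el) in ref
    ]
    n_atoms = len(atoms)
    coords = np.empty((len(frames), n_atoms, 3), dtype=float)
    for fi, frame in enumerate(frames):
        if len(frame) != n_atoms:
            raise InconsistentTrajectoryError(
                f"model {fi + 1} has {len(frame)} atoms, expected {n_atoms}"
            )
        for ai, rec in enumerate(frame):
            if (rec[1], rec[5]) != (atoms[ai].name, atoms[ai].residue_id):
                raise InconsistentTrajectoryError(
                    f"model {fi + 1} atom {ai + 1} is {rec[1]}/{rec[5]}, "
                    f"expected {atoms[ai].name}/{atoms[ai].residue_id}"
                )
            coords[fi, ai] = rec[6]
    if saw_model and len(frames) == 1 and n_atoms == 0:
        raise PDBParseError(f"empty MODEL block in {path}")
    return Structure(atoms=atoms, coords=coords)


def _resolve_altlocs(records: list) -> list:
    """Keep the highest-occupancy altloc per (resid, name); tie → first."""
    best: dict[tuple, int] = {}
    order: list[int] = []
    for i, rec in enumerate(records):
        serial, name, altloc, resname, chain, resid, xyz, occ, el = rec
        if not altloc:
            order.append(i)
            continue
        key = (chain, resid, name)
        if key not in best:
            best[key] = i
            order.append(i)
        elif occ > records[best[key]][7]:
            order[order.index(best[key])] = i
            best[key] = i
    return [records[i] for i in sorted(order)]


def read_trajectory(
    topology: str | Path, coords: str | Path, stride: int = 1
) -> Structure:
    """Read a trajectory, subsampled by ``stride`` (first frame always kept).

    For the required dialect, ``coords`` is a multi-model PDB and
    ``topology`` may equal ``coords``. Binary formats (DCD/XTC/...) are
    handled by MDAnalysis when installed (optional adapter).
    """
    if not isinstance(stride, (int, np.integer)) or stride <= 0:
        raise ValueError(f"stride must be a positive integer, got {stride!r}")
    coords = Path(coords)
    if coords.suffix.lower() == ".pdb":
        s = read_structure(coords)
        if str(topology) != str(coords):
            top = read_structure(topology)
            if top.n_atoms != s.n_atoms:
                raise InconsistentTrajectoryError(
                    f"topology has {top.n_atoms} atoms, coordinates have {s.n_atoms}"
                )
            s = Structure(atoms=top.atoms, coords=s.coords)
        return _stride_structure(s, stride)
    return _read_binary_trajectory(topology, coords, stride)


def _stride_structure(s: Structure, stride: int) -> Structure:
    times = s.frame_times[::stride] if s.frame_times is not None else None
    return Structure(atoms=s.atoms, coords=s.coords[::stride], frame_times=times)


def _read_binary_trajectory(topology, coords, stride: int) -> Structure:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "binary trajectory support requires MDAnalysis "
            "(pip install gpcrswitch[traj])"
        ) from exc
    u = mda.Universe(str(topology), str(coords))
    atoms = [
        Atom(
            serial=int(a.id),
            name=str(a.name),
            element=str(getattr(a, "element", "") or _guess_element(a.name)),
            residue_name=str(a.resname),
            residue_id=int(a.resid),
            chain=str(getattr(a, "segid", "") or ""),
        )
        for a in u.atoms
    ]
    xyz = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    return _stride_structure(Structure(atoms=atoms, coords=xyz), stride)


# ---- structure writing -----------------------------------------------------


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a (multi-model) PDB file.

    Output is byte-deterministic for a given structure; coordinates use the
    standard 3-decimal PDB fields.
    """
    path = Path(path)
    lines: list[str] = []
    multi = s.n_frames > 1
    for fi in range(s.n_frames):
        if multi:
            lines.append(f"MODEL     {fi + 1:4d}")
        for a, (x, y, z) in zip(s.atoms, s.coords[fi]):
            record = "ATOM  " if a.residue_name in _STANDARD_RESNAMES else "HETATM"
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial:5d} {name}{'':1s}{a.residue_name:<4s}"
                f"{a.chain or 'A':1s}{a.residue_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


_STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL HSD HSE HSP".split()
)


# ---- series tables ---------------------------------------------------------


def write_series(table: SeriesTable, path: str | Path) -> None:
    """Write a :class:`SeriesTable` as TSV with a ``# label unit`` header.

    Values are written with 6 decimals and round-trip to 1e-6.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty series table")
    path = Path(path)
    lines = [f"# {table.label}\t{table.unit}"]
    has_time = table.times is not None
    lines.append("frame\ttime_ns\tvalue" if has_time else "frame\tvalue")
    for i, v in enumerate(table.values):
        if has_time:
            lines.append(f"{i}\t{table.times[i]:.6f}\t{v:.6f}")
        else:
            lines.append(f"{i}\t{v:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_series(path: str | Path) -> SeriesTable:
    """Read a TSV written by :func:`write_series`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3 or not lines[0].startswith("# "):
        raise ValueError(f"{path} is not a gpcrswitch series file")
    label, unit = lines[0][2:].split("\t")
    cols = lines[1].split("\t")
    values, times = [], []
    for line in lines[2:]:
        parts = line.split("\t")
        values.append(float(parts[-1]))
        if "time_ns" in cols:
            times.append(float(parts[1]))
    return SeriesTable(
        label=label,
        unit=unit,
        values=np.array(values),
        times=np.array(times) if times else None,
    )
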