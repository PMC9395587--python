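"""Reference computations on deposited structures and sequences.

These are the single-structure worked examples used to validate the
geometry and sequence layers against published values: the chi1 angle of
the 3.36 toggle-switch residue and the R3.50(CZ)-D6.30(CG) ionic-lock
distance in a CB1 crystal structure, and pairwise percent identities of
named sequence pairs. Multi-chain files are handled by using the first
chain that contains every required atom.
"""

from __future__ import annotations

from pathlib import Path

from . import datasets
from .geometry import chi1_series, distance_series
from .io_structures import Structure, read_structure
from .numbering import build_bw_map, resolve
from .sequences import IdentityResult, global_align, percent_identity, read_fasta

__all__ = ["chi1_at_bw", "distance_at_bw", "identity_from_fasta"]


def _chain_with_atoms(s: Structure, needed: list[tuple[int, str]]) -> Structure:
    for chain in s.chains:
        sub = s.chain_subset(chain)
        try:
            for resid, name in needed:
                sub.atom_index(resid, name)
        except KeyError:
            continue
        return sub
    raise KeyError(f"no chain contains all of {needed}")


def _bw_map(annotation_name: str):
    ann = datasets.annotation(annotation_name)
    lo = min(h.first_resid for h in ann)
    hi = max(h.last_resid for h in ann)
    return build_bw_map(ann, (lo, hi))


def chi1_at_bw(
    structure_path: str | Path,
    label: str = "3.36",
    annotation_name: str = "cb1_human",
    frame: int = 0,
) -> float:
    """chi1 (degrees in [0, 360)) of the residue at a generic position."""
    s = read_structure(structure_path)
    resid = resolve(_bw_map(annotation_name), label)
    sub = _chain_with_atoms(s, [(resid, n) for n in ("N", "CA", "CB", "CG")])
    return float(chi1_series(sub, resid).angles[frame])


def distance_at_bw(
    structure_path: str | Path,
    label_a: str = "3.50",
    atom_a: str = "CZ",
    label_b: str = "6.30",
    atom_b: str = "CG",
    annotation_name: str = "cb1_human",
    frame: int = 0,
) -> float:
    """Atom-atom distance (Å) between two generic positions."""
    s = read_structure(structure_path)
    bw = _bw_map(annotation_name)
    ra, rb = resolve(bw, label_a), resolve(bw, label_b)
    sub = _chain_with_atoms(s, [(ra, atom_a), (rb, atom_b)])
    return float(distance_series(sub, (ra, atom_a), (rb, atom_b)).values[frame])


def identity_from_fasta(path_a: str | Path, path_b: str | Path) -> IdentityResult:
    """Percent identity of the first records of two FASTA files."""
    a = read_fasta(path_a)[0]
    b = read_fasta(path_b)[0]
    return percent_identity(global_align(a, b))
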