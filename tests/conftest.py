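import numpy as np
import pytest

from gpcrswitch.io_structures import Atom, Structure


def pdb_line(
    serial, name, resname, resid, x, y, z, chain="A", element=None, record="ATOM",
    altloc=" ", occupancy=1.0,
):
    element = element or name[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {nm}{altloc}{resname:<4s}{chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_model_pdb(tmp_path):
    """3 models x 4 atoms."""
    lines = []
    for model in range(1, 4):
        lines.append(f"MODEL     {model:4d}")
        for i, name in enumerate(["N", "CA", "CB", "CG"], start=1):
            lines.append(pdb_line(i, name, "PHE", 10, float(model), float(i), 0.0))
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "three.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def ten_frame_pdb(tmp_path):
    lines = []
    for model in range(1, 11):
        lines.append(f"MODEL     {model:4d}")
        lines.append(pdb_line(1, "CA", "GLY", 1, float(model), 0.0, 0.0))
        lines.append(pdb_line(2, "CA", "GLY", 2, float(model), 3.0, 0.0))
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "ten.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


def make_structure(atom_specs, coords, frame_times=None):
    """atom_specs: list of (serial, name, element, resname, resid)."""
    atoms = [
        Atom(serial=s, name=n, element=e, residue_name=rn, residue_id=ri, chain="A")
        for s, n, e, rn, ri in atom_specs
    ]
    return Structure(atoms=atoms, coords=np.asarray(coords, dtype=float),
                     frame_times=frame_times)
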