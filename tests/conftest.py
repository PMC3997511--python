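"""Shared fixtures: tiny hand-written PDB texts and small trajectories."""

import numpy as np
import pytest

from iontraj.structio import AtomRecord, Topology, Trajectory

# hand-written 3-atom structure: two protein atoms + one Mg ion
THREE_ATOM_PDB = """\
ATOM      1  CA  GLU A 771       2.000   0.000   0.000  1.00  0.00           C
ATOM      2  OE1 GLU A 771       1.000   2.000   0.000  1.00  0.00           O
HETATM    3 MG   MG  A1001       0.000   0.000   1.500  1.00  0.00          MG
END
"""

# one atom with altloc A and B, plus one plain atom (3 records, 2 atoms kept
# under the "first" policy)
ALTLOC_PDB = """\
ATOM      1  CA AGLU A 771       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BGLU A 771       1.100   0.000   0.000  0.50  0.00           C
ATOM      3  CB  GLU A 771       2.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def make_topology(specs):
    """specs: list of (name, element, resname, resid) tuples."""
    atoms = [
        AtomRecord(serial=i + 1, name=name, element=element, resname=resname,
                   resid=resid)
        for i, (name, element, resname, resid) in enumerate(specs)
    ]
    return Topology.from_atoms(atoms)


def make_trajectory(topology, coords, frame_dt=0.001):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(topology=topology,
                      times=np.arange(coords.shape[0]) * frame_dt,
                      coords=coords)


@pytest.fixture
def octahedron_mg_trajectory():
    """Mg ion at origin with 6 oxygens at exactly 0.20 nm, 3 static frames."""
    top = make_topology(
        [("MG", "MG", "MG", 1001)]
        + [("OE1", "O", "GLU", 771)] * 1
        + [("OE2", "O", "GLU", 771)] * 1
        + [("OD1", "O", "ASP", 800)] * 1
        + [("OD2", "O", "ASP", 800)] * 1
        + [("OD1", "O", "ASN", 796)] * 1
        + [("OH2", "O", "TIP3", 5001)] * 1
    )
    directions = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    frame = np.vstack([[0.0, 0.0, 0.0], 0.20 * directions])
    coords = np.repeat(frame[None], 3, axis=0)
    return make_trajectory(top, coords)
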