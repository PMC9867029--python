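import numpy as np
import pytest
from hypothesis import settings

from ionshell.core_io import Atom, Frame, Topology, Trajectory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_structure(residues, role="protein"):
    """Build (Topology, Frame) from [(resname, resnum, {atom: (x,y,z)}), ...]."""
    atoms, coords = [], []
    for resname, resnum, atom_map in residues:
        for name, xyz in atom_map.items():
            elem = name.lstrip("0123456789")[0]
            atoms.append(
                Atom(len(atoms), name, elem, resname, resnum, "A", role)
            )
            coords.append(xyz)
    return Topology(atoms), Frame(coordinates=np.asarray(coords, float))


def ca_trajectory(coords_per_frame):
    """Trajectory of C-alpha-only residues from an (F, N, 3) array."""
    arr = np.asarray(coords_per_frame, float)
    n_res = arr.shape[1]
    top = Topology(
        [Atom(i, "CA", "C", "ALA", i + 1, "A", "protein") for i in range(n_res)]
    )
    return Trajectory(top, [Frame(coordinates=c) for c in arr])


@pytest.fixture
def five_residue_peptide():
    residues = []
    rng = np.random.default_rng(42)
    names = ["ALA", "GLY", "SER", "THR", "VAL"]
    for i, nm in enumerate(names):
        base = rng.normal(size=3)
        residues.append(
            (nm, i + 1, {"N": tuple(base), "CA": tuple(base + 0.1), "C": tuple(base + 0.2)})
        )
    return make_structure(residues)
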