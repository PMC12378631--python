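import numpy as np
import pytest

from contactsar import synthetic as syn
from contactsar.structure import annotate_groups, read_topology

# Minimal 6-atom pocket: an arginine guanidinium facing a two-atom ligand.
SMALL_TOPOLOGY_PDB = """\
HETATM    1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O1  LIG L   1       1.200   0.000   0.000  1.00  0.00           O
ATOM      3  NE  ARG A 929       4.000   1.200   0.000  1.00  0.00           N
ATOM      4  NH1 ARG A 929       2.800   0.500   0.000  1.00  0.00           N
ATOM      5  NH2 ARG A 929       2.800  -0.900   0.000  1.00  0.00           N
ATOM      6  CZ  ARG A 929       3.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def small_topology():
    return read_topology(SMALL_TOPOLOGY_PDB)


@pytest.fixture
def small_topology_annotated(small_topology):
    return annotate_groups(small_topology)


@pytest.fixture(scope="session")
def default_dataset():
    """Planted SAR dataset at reduced length, shared across unit tests."""
    spec = syn.default_spec(seed=11, frames_per_replicate=400)
    return syn.generate_sar_dataset(spec)


def random_pocket(rng: np.random.Generator, n_atoms: int):
    """Random small topology + trajectory for brute-force oracle tests.

    Atoms are scattered in a 10 A box; roughly the first third are ligand
    atoms.  Elements are drawn from C/N/O/S/H so both the heavy-atom rule
    and the hbond-element filter get exercised.
    """
    from contactsar.structure import AtomRecord, Topology, Trajectory

    n_lig = max(1, n_atoms // 3)
    elements = rng.choice(["C", "N", "O", "S", "H"], size=n_atoms, p=[0.4, 0.2, 0.2, 0.1, 0.1])
    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=f"{elements[i]}{i}",
            element=str(elements[i]),
            residue_name="LIG" if i < n_lig else "ALA",
            residue_number=1 if i < n_lig else 2 + i,
            chain_id="L" if i < n_lig else "A",
            is_ligand=i < n_lig,
        )
        for i in range(n_atoms)
    ]
    # guarantee at least one protein atom
    n_frames = int(rng.integers(1, 6))
    coords = rng.uniform(0.0, 10.0, size=(n_frames, n_atoms, 3))
    return Topology(atoms=atoms), Trajectory(coordinates=coords)
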