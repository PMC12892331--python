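import numpy as np
import pytest

import sitevec as sv


@pytest.fixture(scope="session")
def full_scaffold():
    """Default frequency-7 full sphere (492 directions, 20 Å)."""
    return sv.build_scaffold(7, 20.0)


@pytest.fixture(scope="session")
def hemi_scaffold(full_scaffold):
    """Default hemisphere restriction (260 retained directions)."""
    return sv.restrict_hemisphere(full_scaffold)


@pytest.fixture(scope="session")
def coarse_scaffold():
    """Frequency-2 full sphere (42 directions) for cheap exhaustive checks."""
    return sv.build_scaffold(2, 20.0)


@pytest.fixture(scope="session")
def cavity():
    """Dense hemispherical shell: pocket 8 Å, atoms 1 Å, known 7 Å answer."""
    return sv.make_cavity(pocket_radius=8.0, atom_radius=1.0,
                          shell_density=2.0, seed=11)


def make_atom(coords, radius=1.5, charge=0.0, name="C", element="C",
              residue_name="LIG", residue_id=1):
    return sv.Atom(element=element, name=name, residue_name=residue_name,
                   residue_id=residue_id,
                   coordinates=np.asarray(coords, dtype=float),
                   vdw_radius=radius, partial_charge=charge)


def make_structure(atom_specs, structure_id="test"):
    """Structure from (coords, radius, charge) tuples."""
    atoms = [make_atom(c, r, q, residue_id=i + 1)
             for i, (c, r, q) in enumerate(atom_specs)]
    return sv.Structure(id=structure_id, atoms=atoms)


def constant_descriptor(length, charge=0.0, n=260, structure_id="d",
                        frame_index=0):
    """SiteDescriptor with every vector at the same length/charge."""
    return sv.SiteDescriptor(
        structure_id=structure_id, frame_index=frame_index,
        lengths=np.full(n, float(length)),
        charges=np.full(n, float(charge)),
        hit_atom_index=np.zeros(n, dtype=int))


def descriptor_from_arrays(lengths, charges, structure_id="d", frame_index=0):
    lengths = np.asarray(lengths, dtype=float)
    charges = np.asarray(charges, dtype=float)
    return sv.SiteDescriptor(
        structure_id=structure_id, frame_index=frame_index,
        lengths=lengths, charges=charges,
        hit_atom_index=np.zeros(len(lengths), dtype=int))


def random_descriptor_pair(rng, n=64):
    a = descriptor_from_arrays(rng.uniform(2, 20, n), rng.normal(0, 0.3, n), "a")
    b = descriptor_from_arrays(rng.uniform(2, 20, n), rng.normal(0, 0.3, n), "b")
    return a, b
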