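"""Shared helpers for the test suite."""

import numpy as np
import pytest

from enscreen.core import AtomRecord, Pose, ReceptorConformation


def make_atom(serial, position, name="CA", residue_name="ALA",
              residue_number=None, chain="A", charge=0.0, atom_type="C",
              radius=None):
    return AtomRecord(
        serial=serial, name=name, residue_name=residue_name,
        residue_number=residue_number if residue_number is not None else serial,
        chain=chain, position=np.asarray(position, dtype=float),
        charge=charge, atom_type=atom_type, radius=radius)


def conformation_from_coords(coords, site=True):
    """One-CA-per-residue conformation; selection covers all atoms."""
    coords = np.asarray(coords, dtype=float)
    atoms = [make_atom(i + 1, coords[i]) for i in range(len(coords))]
    selection = [("A", i + 1, "CA") for i in range(len(coords))] if site else ()
    return ReceptorConformation(atoms=atoms, site_selection=selection)


def pose_from_coords(coords, **kwargs):
    coords = np.asarray(coords, dtype=float)
    atoms = [make_atom(i + 1, coords[i], name="C", residue_number=1, chain="L")
             for i in range(len(coords))]
    return Pose(ligand_atoms=atoms, **kwargs)


def random_rotation(rng):
    """Uniform proper rotation matrix from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
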