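import numpy as np
import pytest
from hypothesis import settings

from eiipscreen.interactions import AtomRecord, ComplexStructure

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def admet_rows():
    from eiipscreen.datasets import admet_candidate_rows

    return admet_candidate_rows()


def make_benzene(center, normal, residue=1, is_ligand=False, start_index=0):
    """Regular C6 hexagon (1.39 Å) with explicit ring bonds."""
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for i in range(6):
        ang = i * np.pi / 3
        pos = center + 1.39 * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(
            AtomRecord(
                element="C",
                coords=tuple(pos),
                residue_number=residue,
                residue_name="PHE",
                is_ligand=is_ligand,
                aromatic=True,
                atom_name=f"C{i + 1}",
            )
        )
    bonds = [(start_index + i, start_index + (i + 1) % 6) for i in range(6)]
    return atoms, bonds


def complex_of(atoms, bonds=None):
    return ComplexStructure(atoms=list(atoms), bonds=bonds)
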