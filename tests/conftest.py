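import numpy as np
import pytest

from memprobe.model import AtomRecord, Frame, SystemModel, classify_atoms
from memprobe import synth


@pytest.fixture(scope="session")
def bilayer():
    return synth.make_bilayer(n_per_leaflet=9, tail_carbons=8, seed=11)


@pytest.fixture(scope="session")
def docked(bilayer):
    system, frame, _ = bilayer
    return synth.make_docked_protein((system, frame), n_residues=12,
                                     inserted_loop_residues=(336, 337, 338),
                                     insertion_depth=3.0, seed=12,
                                     n_frames=10, jitter_sigma=0.4)


def build_system(spec, box=None):
    """Helper: spec = list of (name, element, residue_id, residue_name, xyz)."""
    atoms = [AtomRecord(i + 1, name, elem, rid, rname)
             for i, (name, elem, rid, rname, _) in enumerate(spec)]
    coords = np.array([xyz for *_, xyz in spec], dtype=float)
    system = SystemModel(atoms)
    classify_atoms(system)
    frame = Frame(coords, box=None if box is None else np.asarray(box, float))
    return system, frame


@pytest.fixture
def make_system():
    return build_system
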