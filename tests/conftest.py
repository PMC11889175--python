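"""Shared fixtures: toy structures, synthetic trajectories, cycle models."""

from __future__ import annotations

import numpy as np
import pytest

from rnfpump import pump_cycle as pc
from rnfpump import structure_cofactors as sc
from rnfpump import synthetic_data as syn


@pytest.fixture(scope="session")
def toy_complex_dir(tmp_path_factory):
    """Toy complex written to disk once per session (bored membrane)."""
    out = tmp_path_factory.mktemp("toy_complex")
    _, manifest = syn.make_toy_complex(out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def toy_atoms(toy_complex_dir):
    out, manifest = toy_complex_dir
    return sc.load_structure(out / "toy_complex.pdb"), manifest


@pytest.fixture(scope="session")
def toy_network(toy_atoms):
    atoms, manifest = toy_atoms
    return sc.build_network(atoms), manifest


@pytest.fixture(scope="session")
def sealed_complex_dir(tmp_path_factory):
    """Toy complex with the membrane bore disabled (sealed slab)."""
    out = tmp_path_factory.mktemp("sealed_complex")
    _, manifest = syn.make_toy_complex(syn.ToyComplexSpec(bore=False), out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def synthetic_traj():
    """Default two-state trajectory with its ground-truth manifest."""
    return syn.make_two_state_trajectory(syn.SyntheticConfig(seed=20260927 % 2**16))


@pytest.fixture(scope="session")
def canonical_model():
    return pc.build_canonical_cycle()
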