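"""Shared fixtures: toy structures and planted ensembles.

The expensive planted-block ensemble is session-scoped and reused by the
mode, communication and acceptance tests.
"""

import numpy as np
import pytest

from trajcomm import synthetic as syn
from trajcomm.core import StructureModel


@pytest.fixture(scope="session")
def helix100():
    return syn.make_toy_structure(100, "helix", True)


@pytest.fixture(scope="session")
def planted_block_ensemble(helix100):
    """100-residue helix, one correlated block over residues 45-55
    (rho=0.9, sigma=0.1 nm) in 0.01 nm background noise, 2000 frames."""
    spec = syn.PlantedSpec(
        n_residues=100,
        cluster_blocks=[(45, 55, 0.9, 0.1)],
        background_sigma=0.01,
        seed=11,
    )
    return syn.sample_ensemble(helix100, spec, n_frames=2000, n_replicas=1)


@pytest.fixture(scope="session")
def helix110():
    return syn.make_toy_structure(110, "helix", True)


@pytest.fixture(scope="session")
def planted_block_110(helix110):
    """Planted block sized below the 1% pair quantile: 11 of 110 residues
    gives C(11,2)/C(110,2) = 0.92% of residue pairs, so the whole block can
    sit above the LFA threshold."""
    spec = syn.PlantedSpec(
        n_residues=110,
        cluster_blocks=[(45, 55, 0.9, 0.1)],
        background_sigma=0.01,
        seed=11,
    )
    return syn.sample_ensemble(helix110, spec, n_frames=2000, n_replicas=1)


@pytest.fixture
def ext5():
    return syn.make_toy_structure(5, "extended", True)


def ca_only_structure(positions, first_residue=1):
    """Minimal structure with one CA atom per residue at given positions."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return StructureModel(
        atom_ids=np.arange(1, n + 1),
        atom_names=["CA"] * n,
        elements=["C"] * n,
        residue_numbers=np.arange(first_residue, first_residue + n),
        residue_names=["GLY"] * n,
        positions=positions,
    )
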