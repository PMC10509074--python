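"""Shared fixtures.

Small fixtures serve the unit tests; the session-scoped dataset and
benchmark fixtures are expensive and only materialize when the end-to-end
tests request them.
"""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from synthscreen.ligand_chem import Ligand, embed_3d, generate_fixture_ligands
from synthscreen.synth_generator import GenerationConfig
from synthscreen.workflows import BenchmarkSpec, build_unconditioned_complexes, run_benchmark

POOL_SEED = 7
POOL_SIZE = 2500
TEST_SIZE = 500


def ligand_from_smiles(smiles: str, seed: int = 11, lig_id: str = "lig") -> Ligand:
    return embed_3d(Ligand(id=lig_id, mol=Chem.MolFromSmiles(smiles), source=smiles), seed)


def ligand_with_coords(smiles: str, coords: np.ndarray, lig_id: str = "lig") -> Ligand:
    """Ligand whose conformer coordinates are set explicitly (for geometry tests)."""
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, tuple(xyz))
    mol.AddConformer(conf, assignId=True)
    return Ligand(id=lig_id, mol=mol, source=smiles)


@pytest.fixture(scope="session")
def ethanol() -> Ligand:
    return ligand_from_smiles("CCO", seed=5, lig_id="ethanol")


@pytest.fixture(scope="session")
def small_ligands() -> list[Ligand]:
    return generate_fixture_ligands(40, seed=11)


@pytest.fixture(scope="session")
def ligand_pool() -> list[Ligand]:
    return generate_fixture_ligands(POOL_SIZE, seed=POOL_SEED)


@pytest.fixture(scope="session")
def polar_dataset(ligand_pool):
    cfg = GenerationConfig(rule="polar")
    complexes, _ = build_unconditioned_complexes(ligand_pool, cfg, seed=101)
    return complexes


@pytest.fixture(scope="session")
def contribution_dataset(ligand_pool):
    cfg = GenerationConfig(rule="contribution")
    complexes, _ = build_unconditioned_complexes(ligand_pool, cfg, seed=202)
    return complexes


@pytest.fixture(scope="session")
def polar_benchmark(polar_dataset):
    """Full multi-cutoff benchmark on the unbiased polar dataset."""
    spec = BenchmarkSpec(
        rule="polar",
        n_ligands=POOL_SIZE,
        test_size=TEST_SIZE,
        n_attribution_eval=100,
        seed=POOL_SEED,
    )
    return run_benchmark(spec, complexes=polar_dataset)
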