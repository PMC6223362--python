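from __future__ import annotations

import gemmi
import pytest

from structwin.fixtures import FixtureSpec, make_fixture, make_structure
from structwin.structures import parse_structure


@pytest.fixture(scope="session")
def helix3():
    """3-residue ideal helix: structure, PDB text, and parsed-back model."""
    spec = FixtureSpec(n_residues=3, mutation_model="none", seed=11)
    return make_structure(spec)


@pytest.fixture(scope="session")
def helix3_paths(helix3, tmp_path_factory):
    """The 3-residue helix written as .pdb and gemmi-converted .cif files."""
    structure, pdb_text = helix3
    d = tmp_path_factory.mktemp("helix3")
    pdb_path = d / "helix3.pdb"
    pdb_path.write_text(pdb_text)
    cif_path = d / "helix3.cif"
    cif_path.write_text(gemmi.read_pdb_string(pdb_text).make_mmcif_document().as_string())
    return pdb_path, cif_path


@pytest.fixture(scope="session")
def helix10():
    spec = FixtureSpec(n_residues=10, mutation_model="none", seed=5)
    structure, pdb_text = make_structure(spec)
    return structure, pdb_text


@pytest.fixture(scope="session")
def planted_fixture():
    """60-residue helix with a planted balanced cluster at residues 28-32."""
    spec = FixtureSpec(
        n_residues=60,
        n_sequences=24,
        mutation_model="planted-balanced-cluster",
        cluster_residues=frozenset(range(28, 33)),
        seed=7,
    )
    return make_fixture(spec)


@pytest.fixture(scope="session")
def parsed_helix3(helix3_paths):
    pdb_path, _ = helix3_paths
    return parse_structure(pdb_path, format="pdb")
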