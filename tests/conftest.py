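import pytest
from rdkit import Chem

from synthspace.chem_model import standardize_collection
from synthspace.fixtures import FixtureSpec, generate_building_blocks, toy_transform_suite
from synthspace.space import build_space, enumerate_products

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_rows():
    return generate_building_blocks(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def class_of(fixture_rows):
    return {bb_id: cls for _smi, bb_id, cls in fixture_rows}


@pytest.fixture(scope="session")
def bbs(fixture_rows):
    """Standardized building blocks (mol, id) from the synthetic panel."""
    mols = [(Chem.MolFromSmiles(smi), bb_id) for smi, bb_id, _cls in fixture_rows]
    retained, _report = standardize_collection(mols)
    return retained


@pytest.fixture(scope="session")
def suite():
    return toy_transform_suite()


@pytest.fixture(scope="session")
def suite_by_id(suite):
    return {t.transform_id: t for t in suite}


@pytest.fixture(scope="session")
def kill_rulesets(suite):
    return {t.transform_id: t.ruleset() for t in suite if t.kill_ruleset}


@pytest.fixture(scope="session")
def toy_space(bbs, suite, kill_rulesets):
    """The full toy space under the SPACE duplicate policy."""
    space, log = build_space(
        [t.text for t in suite], bbs, kill_rulesets=kill_rulesets, policy="space",
        name="toy",
    )
    return space


@pytest.fixture(scope="session")
def toy_space_lib(bbs, suite, kill_rulesets):
    space, _log = build_space(
        [t.text for t in suite], bbs, kill_rulesets=kill_rulesets, policy="lib2020",
        name="toy-lib",
    )
    return space


@pytest.fixture(scope="session")
def enumerated(toy_space):
    """Full enumeration of the toy space: [(smiles, provenance)]."""
    return list(enumerate_products(toy_space, limit=10**9, seed=0))
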