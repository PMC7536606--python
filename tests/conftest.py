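import pytest

from adrd_diet.assistant import Assistant
from adrd_diet.fixtures import FixtureSpec, load_bundle, write_bundle
from adrd_diet.ontology_kb import (Individual, KnowledgeBase, OntClass,
                                   CaregiverProfile, PatientProfile)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle") / "b1"
    write_bundle(FixtureSpec(seed=1), out)
    return out


@pytest.fixture(scope="session")
def bundle(bundle_dir):
    return load_bundle(bundle_dir)


@pytest.fixture(scope="session")
def kb(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def rules(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def persona(bundle):
    _, _, patients, caregivers, _, _ = bundle
    return patients["p_default"], caregivers["c_default"]


@pytest.fixture(scope="session")
def manifest(bundle):
    return bundle[5]


@pytest.fixture()
def assistant_factory(bundle):
    kb, rules, patients, caregivers, tips, _ = bundle

    def factory(patient="p_default", caregiver="c_default", **kw):
        return Assistant(kb, rules, patients[patient],
                         caregivers[caregiver], tips, **kw)

    return factory


@pytest.fixture()
def toy_kb():
    """Cheese IS-A Dairy IS-A Food, with one cheese individual."""
    kb = KnowledgeBase()
    kb.add_class(OntClass(name="Food", label="Food"))
    kb.add_class(OntClass(name="Dairy", parents=frozenset({"Food"})))
    kb.add_class(OntClass(name="Cheese", parents=frozenset({"Dairy"}),
                          synonyms=frozenset({"cheeses"})))
    kb.add_individual(Individual(id="cheddar", types=frozenset({"Cheese"}),
                                 synonyms=frozenset({"cheddar cheese"})))
    kb.validate()
    return kb


@pytest.fixture()
def simple_patient():
    return PatientProfile(age=70, sex="female", adrd_stage="middle",
                          eer=1800, meals_per_day=3)


@pytest.fixture()
def simple_caregiver():
    return CaregiverProfile(time_limit=60, budget=15)
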