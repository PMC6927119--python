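import numpy as np
import pytest

from knmbp import FixtureConfig, generate_bundle
from knmbp.ontology import CorpusAnnotation, DiseaseDAG


@pytest.fixture
def chain_dag():
    """root <- a <- b with counts f(root)=1, f(a)=2, f(b)=4."""
    dag = DiseaseDAG(["root", "a", "b"], {("a", "root"), ("b", "a")}, "root")
    ann = CorpusAnnotation("chain", {"root": 1, "a": 2, "b": 4})
    return dag, ann


@pytest.fixture
def diamond_dag():
    """root <- {a, b} <- c with counts giving PT(a)=0.5, PT(c)=0.25."""
    dag = DiseaseDAG(
        ["root", "a", "b", "c"],
        {("a", "root"), ("b", "root"), ("c", "a"), ("c", "b")},
        "root",
    )
    ann = CorpusAnnotation("diamond", {"root": 1, "a": 1, "b": 0, "c": 1})
    return dag, ann


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete synthetic study system, shared across tests."""
    config = FixtureConfig(
        n_diseases=25,
        n_mirnas=30,
        n_genes=60,
        latent_rank=3,
        target_set_size=5,
        interaction_density=0.12,
        seed=7,
    )
    return generate_bundle(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
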