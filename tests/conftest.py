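import numpy as np
import pytest

from phylodiet import trees as ptrees
from phylodiet.pipeline import write_study
from phylodiet.simulate import StudyConfig, simulate_study, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tree3():
    """((A:1,B:1):1,C:2) - the workhorse 3-tip example."""
    return ptrees.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree2():
    return ptrees.parse_newick("(A:1,B:1);")


def random_tree(n, seed):
    return simulate_tree(n, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by pipeline-level tests."""
    cfg = StudyConfig(
        n_species=40,
        n_outgroup=8,
        n_trees=5,
        seed=11,
        herbivore_clade_sizes=(4, 3, 2),
        countertrend_size=3,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_paths(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    return write_study(small_study, out)
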