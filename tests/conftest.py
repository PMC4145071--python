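import io as _stdio

import pytest
from hypothesis import HealthCheck, settings
from skbio import TreeNode

from otupick.cluster import ClusteringParams
from otupick.simulate import (SimConfig, extend_tree_with_new_otus,
                              make_benchmark)
from otupick.workflows import (WorkflowParams, pick_classic_open_reference,
                               pick_closed_reference, pick_de_novo,
                               pick_subsampled_open_reference)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def parse_tree(newick: str) -> TreeNode:
    tree = TreeNode.read(_stdio.StringIO(newick))
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


@pytest.fixture(scope="session")
def toy_tree():
    """The worked three-tip tree: ((A:1,B:2):3,C:4):0;"""
    return parse_tree("((A:1,B:2):3,C:4):0;")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_reference_lineages=12, n_novel_lineages=5,
                     n_contaminants=6, n_samples=4, reads_per_sample=250,
                     seed=7)


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return make_benchmark(small_config)


@pytest.fixture(scope="session")
def bench_default():
    """The standard synthetic benchmark (24,000 reads, default config)."""
    return make_benchmark(SimConfig())


@pytest.fixture(scope="session")
def fast_runs(bench_default):
    """All four picking protocols on the standard benchmark, fast preset."""
    b = bench_default
    params = WorkflowParams(seed=11)
    runs = {
        "subsampled": pick_subsampled_open_reference(
            b.reads, b.reference, params, samples=b.samples,
            taxonomy=b.taxonomy),
        "classic": pick_classic_open_reference(
            b.reads, b.reference, params, samples=b.samples,
            taxonomy=b.taxonomy),
        "closed": pick_closed_reference(
            b.reads, b.reference, params, samples=b.samples,
            taxonomy=b.taxonomy),
        "denovo": pick_de_novo(b.reads, params, samples=b.samples),
    }
    return runs


@pytest.fixture(scope="session")
def fast_run_trees(bench_default, fast_runs):
    b = bench_default
    return {name: extend_tree_with_new_otus(b.tree, res, b.truth)
            for name, res in fast_runs.items()
            if name in ("subsampled", "classic")}


@pytest.fixture
def exhaustive_params():
    return ClusteringParams.exhaustive()
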