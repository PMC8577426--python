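import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from metask.fixtures import FixtureSpec, make_expression, make_toy_model


@pytest.fixture(scope="session")
def nested_fixture():
    """Toy model with nested GPRs and decoy routes, plus planted expression."""
    spec = FixtureSpec(
        n_pathways=3,
        pathway_length=3,
        gpr_complexity="nested",
        n_samples=60,
        noise_sd=0.1,
        seed=7,
        decoy_routes=True,
    )
    model, tasks, truth_sets = make_toy_model(spec)
    data, truth = make_expression(spec, model, tasks, truth_sets)
    return spec, model, tasks, truth_sets, data, truth


@pytest.fixture(scope="session")
def simple_chain():
    """Single linear pathway A -> B -> C with a single-gene GPR per step."""
    spec = FixtureSpec(n_pathways=1, pathway_length=2, gpr_complexity="single", seed=0)
    model, tasks, truth_sets = make_toy_model(spec)
    return model, tasks[0], truth_sets
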