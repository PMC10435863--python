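import pytest

from schizocua.parameters import load_reference_parameters


@pytest.fixture(scope="session")
def reference():
    """The embedded reference parameter set: (arms dict, config)."""
    return load_reference_parameters()


@pytest.fixture(scope="session")
def reference_results(reference):
    """Base-case StrategyResult per arm (computed once)."""
    from schizocua.markov import run_cohort

    arms, config = reference
    return {name: run_cohort(arm, config)[1] for name, arm in arms.items()}
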