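import pytest

import sarcocea as sc


@pytest.fixture(scope="session")
def reference_config():
    """Packaged reference configuration: (ParameterSet, [StrategySpec])."""
    return sc.load_reference_config()


@pytest.fixture(scope="session")
def life_table():
    return sc.default_life_table()


@pytest.fixture(scope="session")
def basecase_outcomes(reference_config, life_table):
    params, strategies = reference_config
    return sc.run_strategies(strategies, params, life_table)


@pytest.fixture(scope="session")
def psa_result(reference_config, life_table):
    """A 1000-iteration PSA on the reference configuration, shared across
    tests (about ten seconds to compute)."""
    params, strategies = reference_config
    return sc.run_psa(params, strategies, life_table, n_iterations=1000, seed=20230504)
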