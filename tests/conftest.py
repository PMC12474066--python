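import pandas as pd
import pytest

from hmrisk import core, health, synth


@pytest.fixture(scope="session")
def standards():
    return core.load_reference_standards()


@pytest.fixture(scope="session")
def gen_spec():
    return synth.load_generator_spec(seed=7)


@pytest.fixture(scope="session")
def receptors():
    return health.load_exposure_parameters()


@pytest.fixture(scope="session")
def sediment_means(gen_spec):
    """Published per-metal sediment mean concentrations (mg/kg)."""
    targets = gen_spec.concentrations[core.Medium.SEDIMENT]
    return pd.Series({m: t.mean for m, t in targets.items()})


@pytest.fixture(scope="session")
def water_means(gen_spec):
    """Published per-metal water mean concentrations (ug/L)."""
    targets = gen_spec.concentrations[core.Medium.WATER]
    return pd.Series({m: t.mean for m, t in targets.items()})
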