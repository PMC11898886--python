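from dataclasses import replace

import pytest

import protpanel as pp


@pytest.fixture(scope="session")
def panel():
    return pp.default_panel()


@pytest.fixture(scope="session")
def default_table():
    """Shipped study cohort: 50 healthy / 46 localized / 50 metastatic."""
    return pp.generate_cohort(pp.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_table():
    """A small cohort for fast model fits (12 per group)."""
    return pp.generate_cohort(
        pp.CohortConfig(seed=11, n_healthy=12, n_localized=12, n_metastatic=12)
    )


@pytest.fixture(scope="session")
def zero_noise_panel(panel):
    return replace(
        panel,
        group_sds={p: (0.0, 0.0, 0.0) for p in panel.proteases},
        control_baseline_sd=0.0,
    )


@pytest.fixture(scope="session")
def zero_noise_table(zero_noise_panel):
    return pp.generate_cohort(
        pp.CohortConfig(seed=3, panel=zero_noise_panel, allow_zero_sd=True)
    )
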