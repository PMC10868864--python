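import numpy as np
import pytest

from twinace import phenotypes, synthetic_data
from twinace.cohort_io import apply_exclusions, frame_to_records, records_to_frame
from twinace.synthetic_data import TrueComponents, single_trait_config, simulate_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 1,069-pair defect fixture."""
    return synthetic_data.exclusion_fixture()


@pytest.fixture(scope="session")
def clean_fixture_frame(fixture_cohort):
    """Fixture cohort after exclusions, with derived sips/intent columns."""
    records = frame_to_records(fixture_cohort)
    retained, _ = apply_exclusions(records)
    return phenotypes.derive_traits(records_to_frame(retained))


@pytest.fixture(scope="session")
def continuous_cohort_5k():
    """5,000 pairs, continuous trait, a2=0.5 c2=0.2 e2=0.3, 50/50 zygosity."""
    cfg = single_trait_config(5000, TrueComponents(0.5, 0.2, 0.3),
                              kind="continuous", seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def binary_cohort_10k():
    """10,000 pairs, binary trait (prevalence 0.25), h2=0.5 c2=0.2."""
    cfg = single_trait_config(10_000, TrueComponents(0.5, 0.2, 0.3),
                              kind="binary", prevalence=0.25, seed=12)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def independent_cohort():
    """5,000 pairs with no familial resemblance (e2 = 1), binary."""
    cfg = single_trait_config(5000, TrueComponents(0.0, 0.0, 1.0),
                              kind="binary", prevalence=0.3, seed=13)
    return simulate_cohort(cfg)


def pair_corr(frame, trait, zygosity):
    from twinace.twin_correlations import pair_table

    pt = pair_table(frame, trait)
    sub = pt[pt["zygosity"] == zygosity]
    return float(np.corrcoef(sub["y1"], sub["y2"])[0, 1])
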