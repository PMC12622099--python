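import numpy as np
import pandas as pd
import pytest

from brainage_influence import (
    CohortTable,
    FeatureSpec,
    SyntheticSpec,
    default_adni_like_spec,
    generate_cohort,
)


def make_cohort(ages, labels, features: dict, ids=None) -> CohortTable:
    """Small hand-built cohort for unit tests."""
    n = len(ages)
    if ids is None:
        ids = [f"S{i:03d}" for i in range(n)]
    frame = pd.DataFrame(
        {"age": ages, "label": labels, **features},
        index=pd.Index(ids, name="subject_id"),
    )
    return CohortTable(frame, list(features))


def single_feature_cohort(n, seed, noise_sd=0.0, label="CN", age_range=(50.0, 90.0)):
    """Cohort whose single feature equals age plus optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    feat = ages + (rng.normal(0.0, noise_sd, size=n) if noise_sd else 0.0)
    return make_cohort(ages, [label] * n, {"f": feat})


@pytest.fixture(scope="session")
def adni_like_cohort():
    """One draw of the default synthetic study cohort (870 subjects)."""
    return generate_cohort(default_adni_like_spec(seed=7))


@pytest.fixture
def tiny_spec():
    """A 2-group, 2-feature spec for fast end-to-end paths."""
    return SyntheticSpec(
        n_per_group={"CN": 60, "AD": 40},
        age_range=(55.0, 90.0),
        feature_specs=[
            FeatureSpec("vol", age_slope=-0.03, noise_sd=0.15,
                        group_offsets={"AD": -0.1}, shares_latent=True),
            FeatureSpec("cog", age_slope=-0.005, noise_sd=1.0,
                        group_offsets={"AD": -2.0}),
        ],
        latent_loading=0.05,
        seed=0,
    )
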