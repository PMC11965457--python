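import numpy as np
import pandas as pd
import pytest

from normdev.cohort_sim import (
    CohortSpec,
    DeviationEffect,
    DeviationEffectSpec,
    SiteSpec,
    simulate_clinical_groups,
    simulate_reference_cohort,
)
from normdev.roi import default_roi_dictionary


@pytest.fixture(scope="session")
def small_dictionary():
    """6 regions per cortical modality, 4 subcortical volumes."""
    return default_roi_dictionary(n_cortical=6, n_subcortical=4)


@pytest.fixture(scope="session")
def small_spec(small_dictionary):
    return CohortSpec(
        dictionary=small_dictionary,
        group_sizes={
            "SSD-V": 38,
            "SSD-NV": 138,
            "nonSSD-V": 20,
            "HC": 196,
            "REF": 500,
            "CALIB": 200,
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def reference_cohort(small_spec):
    return simulate_reference_cohort(small_spec)


@pytest.fixture(scope="session")
def clinical_cohort(small_spec):
    effects = DeviationEffectSpec(
        effects=[
            DeviationEffect(
                group="SSD-V",
                roi=small_spec.dictionary.names("thickness")[0],
                modality="thickness",
                shift=-3.0,
                prevalence=0.3,
            )
        ]
    )
    return simulate_clinical_groups(small_spec, effects)


def make_linear_dataset(
    n=300, slope=0.5, intercept=2.0, sigma=0.1, seed=0, sites=("A",), modality="thickness"
):
    """Helper: single-ROI dataset with a linear age trend and Gaussian noise."""
    from normdev.dataio import ROIDataset

    rng = np.random.default_rng(seed)
    age = rng.uniform(10, 80, n)
    site = rng.choice(list(sites), n)
    y = intercept + slope * age + sigma * rng.standard_normal(n)
    idx = pd.Index([f"s{i:04d}" for i in range(n)], name="subject_id")
    values = pd.DataFrame({"roi1": y}, index=idx)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": "M",
            "site": site,
            "group": "REF",
            "icv_mm3": np.nan,
            "pclr_total": np.nan,
        },
        index=idx,
    )
    return ROIDataset(modality, values, cov)
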