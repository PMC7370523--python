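"""Shared fixtures: small simulated trials and fitted models."""

import numpy as np
import pytest

from benefitqq import (
    LongitudinalDataset,
    RELMSpec,
    ScenarioConfig,
    TherapeuticTarget,
    fit_relm,
    predict_random_effects,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def target7():
    return TherapeuticTarget(7.0)


@pytest.fixture(scope="session")
def model1_data():
    """Normal-random-effects trial from the random-intercept/slope model:
    N = 80 patients, visits (0,0,1,2,3,4), one binary covariate."""
    cfg = ScenarioConfig(scenario=1, param=1.0, N=80, n=6, replicates=1, seed=2024)
    rng = np.random.default_rng(2024)
    return simulate_dataset(cfg, rng, arm="reference")


@pytest.fixture(scope="session")
def model1_fit(model1_data):
    return fit_relm(model1_data, RELMSpec(poly_degree_fixed=2, random_terms=(0, 1)))


@pytest.fixture(scope="session")
def model1_eb(model1_fit, model1_data):
    return predict_random_effects(model1_fit, model1_data)


def toy_dataset(times_by_patient, responses_by_patient, covs_by_patient=None):
    """Hand-rolled long dataset; first two visits of each patient are baseline
    when their time is 0, otherwise rows with t=0 are baseline."""
    import pandas as pd

    rows = []
    for i, (ts, ys) in enumerate(zip(times_by_patient, responses_by_patient)):
        x = covs_by_patient[i] if covs_by_patient is not None else None
        for t, y in zip(ts, ys):
            row = {
                "patient_id": f"p{i}",
                "phase": "baseline" if t == 0 else "treatment",
                "time": float(t),
                "response": float(y),
            }
            if x is not None:
                row["x"] = x
            rows.append(row)
    covcols = ("x",) if covs_by_patient is not None else ()
    return LongitudinalDataset(pd.DataFrame(rows), covcols)
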