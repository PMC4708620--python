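"""Shared fixtures: small hand-built and simulated evidence bases."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cemeta as cm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_ds() -> cm.EvidenceDataset:
    """4 estimates / 2 studies / 2 countries with one covariate per level."""
    est = pd.DataFrame(
        {
            "estimate_id": ["E1", "E2", "E3", "E4"],
            "study_id": ["S1", "S1", "S2", "S2"],
            "country_code": ["GBR", "GBR", "DEU", "DEU"],
            "delta_c": [100.0, 120.0, 80.0, 90.0],
            "delta_e": [0.10, 0.12, 0.08, 0.09],
            "is_base_case": [True, False, True, False],
            "d_x": [1.0, 2.0, 3.0, 4.0],
            "d_cat": ["No", "Yes", "No", "Yes"],
        }
    )
    stu = pd.DataFrame(
        {
            "study_id": ["S1", "S2"],
            "year": [2001, 2005],
            "countries": [("GBR",), ("DEU",)],
            "s_z": [10.0, 20.0],
        }
    )
    cty = pd.DataFrame({"country_code": ["GBR", "DEU"], "c_w": [5.0, 15.0]})
    meta = {
        "d_x": cm.CovariateMeta("d_x", "data", "continuous"),
        "d_cat": cm.CovariateMeta("d_cat", "data", "categorical", reference="No", center=False),
        "s_z": cm.CovariateMeta("s_z", "study", "continuous"),
        "c_w": cm.CovariateMeta("c_w", "country", "continuous"),
    }
    return cm.EvidenceDataset(est, stu, cty, meta).validate()


@pytest.fixture(scope="session")
def statins_ds():
    """One draw from the statins-like default generator (seed 1)."""
    cfg = cm.default_statins_config(seed=1)
    ds, truth = cm.simulate_dataset(cfg)
    return ds, truth


def small_config(**overrides) -> cm.SyntheticConfig:
    """A fast nested variance-components configuration for fitting tests."""
    base = dict(
        n_countries=4,
        n_studies=8,
        n_multinational=0,
        estimates_per_study=12,
        beta_c={"intercept": 10.0},
        beta_e={"intercept": 0.5},
        omega_v=np.diag([4.0, 0.04]),
        omega_u=np.diag([9.0, 0.09]),
        omega_e=np.diag([16.0, 0.16]),
        seed=0,
    )
    base.update(overrides)
    return cm.SyntheticConfig(**base)


@pytest.fixture
def small_cfg() -> cm.SyntheticConfig:
    return small_config()


def quick_mcmc(n_iter=600, burn_in=200, seed=0, n_chains=1) -> cm.MCMCConfig:
    return cm.MCMCConfig(n_iter=n_iter, burn_in=burn_in, seed=seed, n_chains=n_chains)
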