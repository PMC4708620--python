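"""Synthetic-data generator: counts, determinism, moments, structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cemeta as cm
from conftest import small_config


def test_counts_forced_by_config():
    cfg = cm.SyntheticConfig(
        n_countries=3, n_studies=6, n_multinational=0, estimates_per_study=10, seed=1
    )
    ds, truth = cm.simulate_dataset(cfg)
    assert ds.n_estimates == 60 and ds.n_studies == 6 and ds.n_countries == 3
    assert truth.v.shape == (3, 2) and truth.u.shape == (6, 2)


def test_degenerate_all_zero():
    cfg = cm.SyntheticConfig(
        n_countries=2,
        n_studies=4,
        estimates_per_study=5,
        omega_v=np.zeros((2, 2)),
        omega_u=np.zeros((2, 2)),
        omega_e=np.zeros((2, 2)),
        seed=2,
    )
    ds, _ = cm.simulate_dataset(cfg)
    assert np.all(ds.estimates["delta_c"] == 0.0)
    assert np.all(ds.estimates["delta_e"] == 0.0)


def test_level1_moments_match_generating_covariance():
    """Monte-Carlo check of the data-level covariance at 10,000 estimates."""
    cfg = cm.SyntheticConfig(
        n_countries=2,
        n_studies=2,
        estimates_per_study=5000,
        omega_v=np.zeros((2, 2)),
        omega_u=np.zeros((2, 2)),
        omega_e=np.array([[4.0, 0.0], [0.0, 1.0]]),
        seed=3,
    )
    ds, _ = cm.simulate_dataset(cfg)
    y = ds.estimates[["delta_c", "delta_e"]].to_numpy()
    S = np.cov(y.T)
    assert S[0, 0] == pytest.approx(4.0, rel=0.05)
    assert S[1, 1] == pytest.approx(1.0, rel=0.05)
    assert abs(S[0, 1]) < 0.05


def test_seed_determinism_and_difference(small_cfg):
    a1, _ = cm.simulate_dataset(small_cfg, seed=7)
    a2, _ = cm.simulate_dataset(small_cfg, seed=7)
    b, _ = cm.simulate_dataset(small_cfg, seed=8)
    pd.testing.assert_frame_equal(a1.estimates, a2.estimates)
    assert not a1.estimates["delta_c"].equals(b.estimates["delta_c"])


def test_multinational_blocks_share_study_effect():
    """With only study-level noise, every estimate of a multinational study
    is identical across its country blocks (one u_j per study)."""
    cfg = cm.SyntheticConfig(
        n_countries=4,
        n_studies=3,
        n_multinational=2,
        countries_per_multinational=2,
        estimates_per_study=8,
        omega_v=np.zeros((2, 2)),
        omega_u=np.diag([1.0, 1.0]),
        omega_e=np.zeros((2, 2)),
        seed=4,
    )
    ds, truth = cm.simulate_dataset(cfg)
    for sid in ds.multinational_studies():
        grp = ds.estimates[ds.estimates["study_id"] == sid]
        assert grp["country_code"].nunique() == 2
        assert grp["delta_c"].nunique() == 1  # same u_j in every block
        assert grp["delta_c"].iloc[0] == pytest.approx(truth.u.loc[sid, "u_c"])


def test_pooled_protocol_removes_country_effect_in_multinational_blocks():
    cfg = cm.SyntheticConfig(
        n_countries=4,
        n_studies=3,
        n_multinational=1,
        countries_per_multinational=2,
        estimates_per_study=6,
        omega_v=np.diag([1.0, 1.0]),
        omega_u=np.zeros((2, 2)),
        omega_e=np.zeros((2, 2)),
        multinational_pooled_protocol=True,
        seed=5,
    )
    ds, truth = cm.simulate_dataset(cfg)
    multi = ds.multinational_studies()[0]
    grp = ds.estimates[ds.estimates["study_id"] == multi]
    assert np.allclose(grp["delta_c"], 0.0)  # v suppressed, u=e=0
    single = ds.estimates[ds.estimates["study_id"] != multi]
    assert not np.allclose(single["delta_c"], 0.0)


def test_default_statins_config_shape_and_moments():
    cfg = cm.default_statins_config()
    assert cfg.n_countries == 23
    assert cfg.n_studies == 67
    assert cfg.n_multinational == 6
    assert sum(
        cfg.estimates_per_study[i] for i in range(61)
    ) == 1806 and sum(cfg.estimates_per_study) == 2094
    tc = cfg.covariate_scheme["d_TC"]
    assert tc["mean"] == 6.676 and tc["sd"] == 1.204
    assert cfg.covariate_scheme["d_age_band"]["levels"]["56-65"] == pytest.approx(0.4117)
    # variance components on the SD scale
    assert np.sqrt(cfg.omega_v[0, 0]) == pytest.approx(5107)
    assert np.sqrt(cfg.omega_e[1, 1]) == pytest.approx(0.501)


def test_empirical_variance_decomposition_matches_omega():
    """ANOVA-type moment estimates from a large nested draw track the
    generating level variances within Monte-Carlo error."""
    cfg = small_config(
        n_countries=30,
        n_studies=150,
        estimates_per_study=30,
        omega_v=np.diag([4.0, 0.04]),
        omega_u=np.diag([9.0, 0.09]),
        omega_e=np.diag([16.0, 0.16]),
    )
    ds, _ = cm.simulate_dataset(cfg, seed=6)
    est = ds.estimates
    y = est["delta_c"].to_numpy()
    study_means = est.groupby("study_id")["delta_c"].transform("mean").to_numpy()
    within = y - study_means
    # within-study variance ~ omega_e[0,0]
    assert within.var() == pytest.approx(16.0, rel=0.15)
    cmeans = est.groupby("country_code")["delta_c"].mean()
    # between-country spread ~ omega_v + omega_u/(studies per country) + ...
    assert cmeans.var() == pytest.approx(4.0 + 9.0 / 5.0, rel=0.6)


def test_non_pd_covariance_is_config_error():
    cfg = cm.SyntheticConfig(omega_e=np.array([[1.0, 2.0], [2.0, 1.0]]))
    with pytest.raises(ValueError):
        cfg.validate()


def test_recovery_report_deterministic(small_cfg):
    mc = cm.MCMCConfig(n_iter=150, burn_in=50, n_chains=1, seed=0)
    r1 = cm.recovery_experiment(small_cfg, mcmc=mc, n_replicates=1, seed=3)
    r2 = cm.recovery_experiment(small_cfg, mcmc=mc, n_replicates=1, seed=3)
    pd.testing.assert_frame_equal(r1.params, r2.params)
    assert r1.n_flagged == 0
    assert "beta:cost:intercept" in r1.params.index
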