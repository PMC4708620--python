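"""VPCs, DIC, fit summaries, and shrunken residuals."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cemeta as cm
from cemeta.design import build_design
from cemeta.gibbs import conditional_deviance, run_chain
from conftest import small_config, quick_mcmc


def test_vpc_equal_variances_symmetric():
    vpc = cm.compute_vpc(np.eye(2), np.eye(2), np.eye(2))
    np.testing.assert_allclose(vpc.to_numpy(), 100.0 / 3.0)
    np.testing.assert_allclose(vpc.sum(axis=0).to_numpy(), 100.0)


def test_vpc_accepts_matrices_and_diagonals():
    a = cm.compute_vpc(np.diag([4.0, 1.0]), np.diag([4.0, 1.0]), np.diag([8.0, 2.0]))
    b = cm.compute_vpc(np.array([4.0, 1.0]), np.array([4.0, 1.0]), np.array([8.0, 2.0]))
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy())
    assert a.loc["data", "cost"] == pytest.approx(50.0)


def test_vpc_negative_variance_is_error():
    with pytest.raises(ValueError):
        cm.compute_vpc(np.diag([-1.0, 1.0]), np.eye(2), np.eye(2))


@given(c=st.floats(1e-3, 1e6))
def test_vpc_scale_consistency(c):
    base = cm.compute_vpc(np.diag([2.0, 1.0]), np.diag([3.0, 1.0]), np.diag([5.0, 1.0]))
    scaled = cm.compute_vpc(
        np.diag([2.0 * c, 1.0]), np.diag([3.0 * c, 1.0]), np.diag([5.0 * c, 1.0])
    )
    np.testing.assert_allclose(base["cost"], scaled["cost"], rtol=1e-9)


# ---------------------------------------------------------------------------
# DIC


def _small_fit(seed=0, **cfg_over):
    cfg = small_config(**cfg_over)
    ds, truth = cm.simulate_dataset(cfg, seed=seed)
    fit = cm.fit_model(ds, cm.ModelSpec("cross_classified"), mcmc=quick_mcmc(seed=seed))
    return ds, truth, fit


def test_deviance_doubles_when_data_duplicated():
    cfg = small_config(n_countries=2, n_studies=4, estimates_per_study=6)
    ds, _ = cm.simulate_dataset(cfg, seed=1)
    bundle = build_design(ds, cm.ModelSpec("cross_classified"))
    doubled = ds.copy()
    dup = ds.estimates.copy()
    dup["estimate_id"] = dup["estimate_id"] + "_b"
    doubled.estimates = (
        __import__("pandas").concat([ds.estimates, dup]).reset_index(drop=True)
    )
    bundle2 = build_design(doubled, cm.ModelSpec("cross_classified"))
    beta = np.array([1.0, 2.0])
    v = np.zeros((bundle.n_countries, 2))
    u = np.zeros((bundle.n_studies, 2))
    om = np.array([[2.0, 0.3], [0.3, 1.0]])
    d1 = conditional_deviance(bundle, beta, v, u, om)
    d2 = conditional_deviance(bundle2, beta, v, u, om)
    assert d2 == pytest.approx(2.0 * d1)


def test_dic_singular_omega_errors():
    cfg = small_config(n_countries=2, n_studies=4, estimates_per_study=6)
    ds, _ = cm.simulate_dataset(cfg, seed=1)
    bundle = build_design(ds, cm.ModelSpec("cross_classified"))
    with pytest.raises(ValueError, match="singular"):
        conditional_deviance(
            bundle, np.zeros(2), np.zeros((4, 2)), np.zeros((8, 2)), np.zeros((2, 2))
        )


# ---------------------------------------------------------------------------
# fit summaries


def test_summary_vpc_rows_sum_to_100_and_intervals_cover_truth():
    ds, truth, fit = _small_fit(seed=3)
    np.testing.assert_allclose(fit.vpc.sum(axis=0).to_numpy(), 100.0, atol=1e-6)
    fe = fit.fixed_effects
    assert set(fe.columns) >= {"mean", "sd", "lo95", "hi95", "stars"}
    assert fit.n_data == ds.n_estimates
    # sigma table is on the SD scale
    assert fit.sigma_table().loc["data", "cost"] == pytest.approx(
        np.sqrt(fit.omega["e"][0, 0])
    )


def test_significance_stars_on_strong_effect():
    ds, truth, fit = _small_fit(seed=5)
    # intercept of 10 with these variances is overwhelmingly nonzero
    assert fit.fixed_effects.loc["cost:intercept", "stars"] == "***"


def test_shrunken_residuals_shrink_toward_zero():
    """Posterior mean study effects lie between 0 and the raw mean residual."""
    cfg = small_config(n_studies=10, estimates_per_study=15)
    ds, _ = cm.simulate_dataset(cfg, seed=7)
    fit = cm.fit_model(
        ds, cm.ModelSpec("cross_classified"), mcmc=quick_mcmc(n_iter=800, seed=7)
    )
    res = cm.shrunken_residuals(fit.chains, fit.bundle, "study")
    est = ds.estimates
    grand_c = fit.fixed_effects.loc["cost:intercept", "mean"]
    v_mean = fit.chains.pooled(fit.chains.v).mean(axis=0)
    v_of = {c: v_mean[i, 0] for i, c in enumerate(fit.bundle.country_ids)}
    study_country = est.groupby("study_id")["country_code"].first()
    raw = (
        est.groupby("study_id")["delta_c"].mean()
        - grand_c
        - study_country.map(v_of)
    )
    agree = 0
    for sid in res.table.index:
        shrunk = res.table.loc[sid, "cost_mean"]
        r = raw.loc[sid]
        if abs(shrunk) <= abs(r) + 1e-6 and np.sign(shrunk) == np.sign(r):
            agree += 1
    assert agree >= 8  # allow a couple of near-zero sign flips


def test_residual_rank_and_extreme_country():
    """A planted extreme country ranks last with interval excluding zero."""
    cfg = small_config(n_countries=6, n_studies=12, estimates_per_study=15)
    ds, _ = cm.simulate_dataset(cfg, seed=9)
    bump = ds.estimates["country_code"] == "AAA"
    ds.estimates.loc[bump, "delta_c"] += 40.0
    fit = cm.fit_model(
        ds, cm.ModelSpec("cross_classified"), mcmc=quick_mcmc(n_iter=800, seed=9)
    )
    res = cm.shrunken_residuals(fit.chains, fit.bundle, "country")
    tab = res.table
    assert tab.loc["AAA", "rank"] == len(tab)
    assert tab.loc["AAA", "cost_lo95"] > 0
    assert set(tab["rank"]) == set(range(1, len(tab) + 1))


def test_residuals_include_pooled_group_under_hybrid(statins_ds):
    ds, _ = statins_ds
    fit = cm.fit_model(
        ds, cm.ModelSpec("hybrid"), mcmc=quick_mcmc(n_iter=300, burn_in=100, seed=2)
    )
    res = cm.shrunken_residuals(fit.chains, fit.bundle, "country")
    assert cm.POOLED_COUNTRY_LABEL in res.table.index
    assert len(res.table) == 18
    with pytest.raises(ValueError, match="unknown residual level"):
        cm.shrunken_residuals(fit.chains, fit.bundle, "continent")
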