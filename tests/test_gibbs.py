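"""Gibbs sampler: determinism, PD draws, GLS consistency, diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cemeta as cm
from cemeta.design import Priors, build_design
from cemeta.gibbs import run_chain
from conftest import small_config, quick_mcmc


def _nested_bundle(seed=0, **overrides):
    cfg = small_config(**overrides)
    ds, _ = cm.simulate_dataset(cfg, seed=seed)
    return build_design(ds, cm.ModelSpec("cross_classified"))


def test_same_seed_bit_identical():
    bundle = _nested_bundle()
    pri = cm.default_priors(bundle)
    c1 = run_chain(bundle, pri, quick_mcmc(n_iter=100, burn_in=30, seed=11))
    c2 = run_chain(bundle, pri, quick_mcmc(n_iter=100, burn_in=30, seed=11))
    np.testing.assert_array_equal(c1.beta, c2.beta)
    np.testing.assert_array_equal(c1.omega_e, c2.omega_e)
    c3 = run_chain(bundle, pri, quick_mcmc(n_iter=100, burn_in=30, seed=12))
    assert not np.array_equal(c1.beta, c3.beta)


def test_all_stored_omegas_positive_definite():
    bundle = _nested_bundle()
    chains = run_chain(bundle, cm.default_priors(bundle), quick_mcmc(n_iter=200, burn_in=50, seed=2))
    for arr in (chains.omega_v, chains.omega_u, chains.omega_e):
        flat = arr.reshape(-1, 2, 2)
        eig = np.linalg.eigvalsh(flat)
        assert eig.min() > 0


def test_posterior_beta_matches_gls_with_pinned_covariances():
    """With all covariance matrices pinned at truth and a flat coefficient
    prior, the posterior mean of the intercept matches the closed-form GLS
    estimate (cluster-mean weighting) within 1%."""
    rng = np.random.default_rng(42)
    J, n_per = 40, 50  # 2000 estimates
    su2, se2 = 9.0, 4.0
    u = rng.normal(0, np.sqrt(su2), J)
    dc = np.repeat(10.0 + u, n_per) + rng.normal(0, np.sqrt(se2), J * n_per)
    de = rng.normal(0.0, 1.0, J * n_per)
    est = pd.DataFrame(
        {
            "estimate_id": [f"E{i}" for i in range(J * n_per)],
            "study_id": np.repeat([f"S{j:02d}" for j in range(J)], n_per),
            "country_code": "AAA",
            "delta_c": dc,
            "delta_e": de,
            "is_base_case": False,
        }
    )
    stu = pd.DataFrame(
        {
            "study_id": [f"S{j:02d}" for j in range(J)],
            "year": 2000,
            "countries": [("AAA",)] * J,
        }
    )
    cty = pd.DataFrame({"country_code": ["AAA"]})
    ds = cm.EvidenceDataset(est, stu, cty, {}).validate()
    bundle = build_design(ds, cm.ModelSpec("cross_classified"))
    pri = Priors(
        beta_mean=np.zeros(2),
        beta_precision=np.zeros(2),
        pin_omega_v=np.zeros((2, 2)),
        pin_omega_u=np.array([[su2, 0.0], [0.0, 1e-8]]),
        pin_omega_e=np.array([[se2, 0.0], [0.0, 1.0]]),
    )
    chains = run_chain(bundle, pri, quick_mcmc(n_iter=2000, burn_in=300, seed=3))
    post_mean = chains.pooled(chains.beta)[:, 0].mean()
    gls = est.groupby("study_id")["delta_c"].mean().mean()  # balanced design
    assert post_mean == pytest.approx(gls, rel=0.01)


def test_refuses_free_omega_with_single_cluster():
    bundle = _nested_bundle(n_countries=1, n_studies=4, estimates_per_study=5)
    pri = cm.default_priors(bundle)
    with pytest.raises(RuntimeError, match="country"):
        run_chain(bundle, pri, quick_mcmc(n_iter=50, burn_in=10))
    pri.pin_omega_v = np.zeros((2, 2))
    chains = run_chain(bundle, pri, quick_mcmc(n_iter=50, burn_in=10))
    assert np.all(chains.v == 0.0)


def _fake_chains(beta: np.ndarray) -> cm.PosteriorChains:
    n_chains, T = beta.shape[:2]
    eye = np.broadcast_to(np.eye(2), (n_chains, T, 2, 2)).copy()
    return cm.PosteriorChains(
        beta=beta,
        v=np.zeros((n_chains, T, 1, 2)),
        u=np.zeros((n_chains, T, 1, 2)),
        omega_v=eye,
        omega_u=eye.copy(),
        omega_e=eye.copy(),
        deviance=np.zeros((n_chains, T)),
        coef_names=("cost:intercept",),
        country_ids=("AAA",),
        study_ids=("S1",),
        config=cm.MCMCConfig(n_iter=T, burn_in=1, n_chains=n_chains, seed=0),
    )


def test_diagnostics_iid_trending_and_constant():
    rng = np.random.default_rng(0)
    iid = _fake_chains(rng.standard_normal((2, 1000, 1)))
    d = cm.diagnostics(iid)
    assert d.loc["beta:cost:intercept", "rhat"] == pytest.approx(1.0, abs=0.02)
    assert not d.loc["beta:cost:intercept", "flagged"]
    # constant covariance entries are flagged as undefined, ESS capped
    assert d.loc["var:country:cost", "flagged"]
    assert d.loc["var:country:cost", "ess"] <= 2000

    trend = _fake_chains(np.linspace(0, 5, 2000).reshape(2, 1000, 1))
    d2 = cm.diagnostics(trend)
    assert d2.loc["beta:cost:intercept", "flagged"]
    assert d2.loc["beta:cost:intercept", "rhat"] > 1.05


def test_chain_export_long_format():
    bundle = _nested_bundle()
    chains = run_chain(
        bundle, cm.default_priors(bundle), quick_mcmc(n_iter=20, burn_in=5, seed=1)
    )
    tab = chains.to_frame()
    assert set(tab.columns) == {"chain", "iteration", "parameter", "value"}
    n_params = len(chains.scalar_draws())
    assert len(tab) == n_params * 20
    assert tab["value"].notna().all()


def test_diagnostics_requires_draws():
    few = _fake_chains(np.zeros((1, 5, 1)))
    with pytest.raises(ValueError, match="10"):
        cm.diagnostics(few)
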