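"""Gibbs sampler for the bivariate random-intercept model.

All full conditionals are conjugate, so the sampler is a pure Gibbs scheme
with a systematic scan per sweep:

1. coefficients β | · — multivariate normal, generalised-least-squares
   form with the level-1 covariance Ω_e and the (possibly flat) normal
   prior;
2. country effects v_k | · and study effects u_j | · — independent
   bivariate normals per cluster, pooling that cluster's level-1
   residuals against the level's covariance matrix;
3. covariance matrices Ω_v, Ω_u, Ω_e | · — inverse-Wishart with degrees
   of freedom df0 + m and scale S0 + Σ r rᵀ over the m effects (or the N
   data residual pairs for Ω_e).

The scan order does not affect the stationary distribution.  Each chain
has its own pseudo-random stream spawned from (seed, chain index), so runs
are reproducible draw-for-draw.  The conditional deviance −2 log p(y | β,
v, u, Ω_e) is accumulated at every stored sweep for DIC computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .design import DesignBundle, Priors

__all__ = ["MCMCConfig", "PosteriorChains", "run_chain", "diagnostics"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MCMCConfig:
    """Chain-length and initialisation settings.

    ``n_iter`` counts stored post-burn-in sweeps per chain (before
    thinning); ``init='moment'`` starts β at the OLS solution and the
    covariances at their prior scale / df, ``init='zero'`` starts β and
    the effects at zero with identity covariances.
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    n_chains: int = 2
    init: str = "moment"

    def __post_init__(self) -> None:
        if min(self.n_iter, self.burn_in + 1, self.thin, self.n_chains) < 1:
            raise ValueError("all MCMC counts must be positive (thin >= 1)")
        if self.init not in ("moment", "zero"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def n_stored(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorChains:
    """Stored Gibbs draws: one leading axis per chain, one per kept sweep."""

    beta: np.ndarray  # (chains, T, p)
    v: np.ndarray  # (chains, T, K, 2)
    u: np.ndarray  # (chains, T, J, 2)
    omega_v: np.ndarray  # (chains, T, 2, 2)
    omega_u: np.ndarray
    omega_e: np.ndarray
    deviance: np.ndarray  # (chains, T)
    coef_names: tuple[str, ...]
    country_ids: tuple[str, ...]
    study_ids: tuple[str, ...]
    config: MCMCConfig
    pinned: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_stored(self) -> int:
        return self.beta.shape[1]

    def pooled(self, arr: np.ndarray) -> np.ndarray:
        """Merge the chain axis into the draw axis."""
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Chain-shaped (chains, T) arrays for every scalar parameter."""
        out: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.coef_names):
            out[f"beta:{name}"] = self.beta[:, :, i]
        for tag, arr in (
            ("country", self.omega_v),
            ("study", self.omega_u),
            ("data", self.omega_e),
        ):
            out[f"var:{tag}:cost"] = arr[:, :, 0, 0]
            out[f"cov:{tag}"] = arr[:, :, 0, 1]
            out[f"var:{tag}:effect"] = arr[:, :, 1, 1]
        return out

    def to_frame(self):
        """Long-format draws: columns chain, iteration, parameter, value."""
        import pandas as pd

        frames = []
        for name, arr in self.scalar_draws().items():
            for c in range(self.n_chains):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(self.n_stored),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# small 2x2 helpers (vectorised over a leading cluster axis)


def _inv2(m: np.ndarray) -> np.ndarray:
    a, b, c, d = m[..., 0, 0], m[..., 0, 1], m[..., 1, 0], m[..., 1, 1]
    det = a * d - b * c
    out = np.empty_like(m)
    out[..., 0, 0] = d / det
    out[..., 0, 1] = -b / det
    out[..., 1, 0] = -c / det
    out[..., 1, 1] = a / det
    return out


def _chol2(m: np.ndarray) -> np.ndarray:
    """Lower Cholesky of a stack of SPD 2x2 matrices."""
    l11 = np.sqrt(m[..., 0, 0])
    l21 = m[..., 1, 0] / l11
    l22 = np.sqrt(m[..., 1, 1] - l21 * l21)
    out = np.zeros_like(m)
    out[..., 0, 0] = l11
    out[..., 1, 0] = l21
    out[..., 1, 1] = l22
    return out


def _is_spd2(m: np.ndarray) -> bool:
    return (
        m[0, 0] > 0
        and m[1, 1] > 0
        and (m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]) > 0
    )


def _sample_cluster_effects(
    resid_sums: np.ndarray,
    counts: np.ndarray,
    W: np.ndarray,
    omega_inv: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw all of a level's bivariate effects from their full conditionals.

    Per cluster: precision = n_k W + Ω⁻¹, mean = precision⁻¹ (W · Σ resid).
    """
    prec = counts[:, None, None] * W[None, :, :] + omega_inv[None, :, :]
    cov = _inv2(prec)
    lin = resid_sums @ W.T  # (K, 2): W Σr  (W symmetric)
    mean = np.einsum("kab,kb->ka", cov, lin)
    L = _chol2(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("kab,kb->ka", L, z)


def _group_sums(resid: np.ndarray, index: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((k, 2))
    np.add.at(out, index, resid)
    return out


def _translate_level(
    beta: np.ndarray,
    effects: np.ndarray,
    omega: np.ndarray,
    prior_prec: np.ndarray,
    prior_mean: np.ndarray,
    intercept_idx: dict[int, int],
    rng: np.random.Generator,
) -> None:
    """Conjugate translation move between intercepts and one level's effects.

    The likelihood is invariant under shifting every effect of a level by
    δ while subtracting δ from the corresponding intercepts, so δ can be
    Gibbs-sampled from the (Gaussian) density of the shifted state — the
    translation-group generalised-Gibbs move.  This breaks the strong
    posterior correlation between intercepts and effect means that makes
    the plain scan mix slowly.  Mutates ``beta`` and ``effects`` in place.
    ``intercept_idx`` maps response component (0=ΔC, 1=ΔE) to the
    intercept's column in β; responses without an intercept are held fixed.
    """
    dims = sorted(intercept_idx)
    if not dims:
        return
    m = len(effects)
    om_inv = _inv2(omega)
    prec_full = m * om_inv
    lin_full = -om_inv @ effects.sum(axis=0)
    T = np.zeros((2, 2))
    shift_resid = np.zeros(2)
    for d, idx in intercept_idx.items():
        T[d, d] = prior_prec[idx]
        shift_resid[d] = beta[idx] - prior_mean[idx]
    prec_full = prec_full + T
    lin_full = lin_full + T @ shift_resid
    P = prec_full[np.ix_(dims, dims)]
    b = lin_full[dims]
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    delta_active = mean + np.linalg.solve(L.T, rng.standard_normal(len(dims)))
    delta = np.zeros(2)
    delta[dims] = delta_active
    effects += delta
    for d, idx in intercept_idx.items():
        beta[idx] -= delta[d]


def _translate_nested(
    v: np.ndarray,
    u: np.ndarray,
    omega_v: np.ndarray,
    omega_u: np.ndarray,
    j_to_k: np.ndarray,
    studies_per_k: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Translation move between country effects and their studies' effects.

    On nested data the likelihood only identifies v_k + mean(u_j : j in k),
    so per country a shift δ_k with u_j → u_j + δ_k, v_k → v_k − δ_k is
    sampled from its Gaussian conditional (precision m_k Ω_u⁻¹ + Ω_v⁻¹).
    Mutates ``v`` and ``u`` in place.
    """
    K = len(v)
    ou_inv = _inv2(omega_u)
    ov_inv = _inv2(omega_v)
    u_sums = np.zeros((K, 2))
    np.add.at(u_sums, j_to_k, u)
    prec = studies_per_k[:, None, None] * ou_inv[None] + ov_inv[None]
    cov = _inv2(prec)
    lin = -(u_sums @ ou_inv.T) + v @ ov_inv.T
    mean = np.einsum("kab,kb->ka", cov, lin)
    L = _chol2(cov)
    delta = mean + np.einsum("kab,kb->ka", L, rng.standard_normal((K, 2)))
    u += delta[j_to_k]
    v -= delta


def run_chain(bundle: DesignBundle, priors: Priors, cfg: MCMCConfig) -> PosteriorChains:
    """Run the Gibbs sampler; deterministic given ``cfg.seed``.

    A level whose covariance matrix is free to be sampled must have at
    least two clusters; with fewer, pin that level's matrix via the priors
    (pinning to exact zero removes the level).  Raises ``RuntimeError``
    naming the sweep if the state becomes non-finite.
    """
    priors.validate()
    n, p = bundle.n, bundle.p
    K, J = bundle.n_countries, bundle.n_studies
    pin_v, pin_u, pin_e = (
        priors.pin_omega_v,
        priors.pin_omega_u,
        priors.pin_omega_e,
    )
    zero_v = pin_v is not None and not np.any(pin_v)
    zero_u = pin_u is not None and not np.any(pin_u)
    if pin_e is not None and not _is_spd2(np.asarray(pin_e, dtype=float)):
        raise ValueError("pinned omega_e must be positive definite")
    for label, kk, pin in (("country", K, pin_v), ("study", J, pin_u)):
        if pin is None and kk < 2:
            raise RuntimeError(
                f"cannot estimate the {label}-level covariance from {kk} "
                f"cluster(s); pin that level's omega (e.g. to zero) or pool"
            )

    # fixed sufficient statistics for the beta update
    G11 = bundle.Xc.T @ bundle.Xc
    G12 = bundle.Xc.T @ bundle.Xe
    G22 = bundle.Xe.T @ bundle.Xe
    y2 = bundle.y2
    j_idx, k_idx = bundle.study_index, bundle.country_index
    n_per_k = np.bincount(k_idx, minlength=K).astype(float)
    n_per_j = np.bincount(j_idx, minlength=J).astype(float)
    prior_prec = np.asarray(priors.beta_precision, dtype=float)
    if prior_prec.ndim == 0:
        prior_prec = np.full(p, float(prior_prec))
    prior_mean = np.asarray(priors.beta_mean, dtype=float)

    beta_ols, *_ = np.linalg.lstsq(bundle.X, bundle.y, rcond=None)

    intercept_idx = {
        d: bundle.coef_names.index(f"{resp}:intercept")
        for d, resp in enumerate(("cost", "effect"))
        if f"{resp}:intercept" in bundle.coef_names
    }
    nested_map = bundle.study_to_country()
    if nested_map is not None and not (zero_v or zero_u):
        j_to_k = np.array([nested_map[j] for j in range(J)], dtype=int)
        studies_per_k = np.bincount(j_to_k, minlength=K).astype(float)
        if studies_per_k.min() < 1:  # a country with no studies: skip the move
            nested_map = None
    else:
        nested_map = None

    T = cfg.n_stored
    chains = PosteriorChains(
        beta=np.empty((cfg.n_chains, T, p)),
        v=np.empty((cfg.n_chains, T, K, 2)),
        u=np.empty((cfg.n_chains, T, J, 2)),
        omega_v=np.empty((cfg.n_chains, T, 2, 2)),
        omega_u=np.empty((cfg.n_chains, T, 2, 2)),
        omega_e=np.empty((cfg.n_chains, T, 2, 2)),
        deviance=np.empty((cfg.n_chains, T)),
        coef_names=bundle.coef_names,
        country_ids=bundle.country_ids,
        study_ids=bundle.study_ids,
        config=cfg,
        pinned={"v": pin_v, "u": pin_u, "e": pin_e},
    )

    seed_seq = np.random.SeedSequence(cfg.seed)
    for c, child in enumerate(seed_seq.spawn(cfg.n_chains)):
        rng = np.random.default_rng(child)
        # initial state
        if cfg.init == "moment":
            beta = beta_ols.copy()
            om_v = np.asarray(pin_v, float) if pin_v is not None else priors.scale_v / priors.df_v
            om_u = np.asarray(pin_u, float) if pin_u is not None else priors.scale_u / priors.df_u
            om_e = np.asarray(pin_e, float) if pin_e is not None else priors.scale_e / priors.df_e
        else:
            beta = np.zeros(p)
            om_v = np.asarray(pin_v, float) if pin_v is not None else np.eye(2)
            om_u = np.asarray(pin_u, float) if pin_u is not None else np.eye(2)
            om_e = np.asarray(pin_e, float) if pin_e is not None else np.eye(2)
        v = np.zeros((K, 2))
        u = np.zeros((J, 2))

        stored = 0
        total = cfg.burn_in + cfg.n_iter
        for t in range(total):
            W = _inv2(om_e)

            # --- beta ---
            R = y2 - v[k_idx] - u[j_idx]
            A = (
                W[0, 0] * G11
                + W[0, 1] * (G12 + G12.T)
                + W[1, 1] * G22
                + np.diag(prior_prec)
            )
            b = (
                bundle.Xc.T @ (W[0, 0] * R[:, 0] + W[0, 1] * R[:, 1])
                + bundle.Xe.T @ (W[0, 1] * R[:, 0] + W[1, 1] * R[:, 1])
                + prior_prec * prior_mean
            )
            La = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            beta = mean + np.linalg.solve(La.T, rng.standard_normal(p))
            F = np.column_stack([bundle.Xc @ beta, bundle.Xe @ beta])

            # --- country effects ---
            if zero_v:
                v[:] = 0.0
            else:
                resid = y2 - F - u[j_idx]
                v = _sample_cluster_effects(
                    _group_sums(resid, k_idx, K), n_per_k, W, _inv2(om_v), rng
                )
                _translate_level(
                    beta, v, om_v, prior_prec, prior_mean, intercept_idx, rng
                )
                F = np.column_stack([bundle.Xc @ beta, bundle.Xe @ beta])

            # --- study effects ---
            if zero_u:
                u[:] = 0.0
            else:
                resid = y2 - F - v[k_idx]
                u = _sample_cluster_effects(
                    _group_sums(resid, j_idx, J), n_per_j, W, _inv2(om_u), rng
                )
                _translate_level(
                    beta, u, om_u, prior_prec, prior_mean, intercept_idx, rng
                )
                F = np.column_stack([bundle.Xc @ beta, bundle.Xe @ beta])
                if nested_map is not None:
                    _translate_nested(v, u, om_v, om_u, j_to_k, studies_per_k, rng)

            # --- covariance matrices ---
            if pin_v is None:
                om_v = stats.invwishart.rvs(
                    df=priors.df_v + K, scale=priors.scale_v + v.T @ v, random_state=rng
                )
            if pin_u is None:
                om_u = stats.invwishart.rvs(
                    df=priors.df_u + J, scale=priors.scale_u + u.T @ u, random_state=rng
                )
            E = y2 - F - v[k_idx] - u[j_idx]
            if pin_e is None:
                om_e = stats.invwishart.rvs(
                    df=priors.df_e + n, scale=priors.scale_e + E.T @ E, random_state=rng
                )

            if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(om_e))):
                raise RuntimeError(f"non-finite sampler state at sweep {t}")

            if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
                for label, m in (("v", om_v), ("u", om_u), ("e", om_e)):
                    if not (label == "v" and zero_v) and not (label == "u" and zero_u):
                        if not _is_spd2(np.asarray(m, float)):
                            raise RuntimeError(
                                f"omega_{label} draw not positive definite at sweep {t}"
                            )
                We = _inv2(om_e)
                dev = bundle.n * (2.0 * _LOG_2PI + _logdet2(om_e)) + float(
                    np.einsum("na,ab,nb->", E, We, E)
                )
                chains.beta[c, stored] = beta
                chains.v[c, stored] = v
                chains.u[c, stored] = u
                chains.omega_v[c, stored] = om_v
                chains.omega_u[c, stored] = om_u
                chains.omega_e[c, stored] = om_e
                chains.deviance[c, stored] = dev
                stored += 1
    return chains


def _logdet2(m: np.ndarray) -> float:
    return float(np.log(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]))


def conditional_deviance(
    bundle: DesignBundle,
    beta: np.ndarray,
    v: np.ndarray,
    u: np.ndarray,
    omega_e: np.ndarray,
) -> float:
    """−2 log BVN likelihood of the level-1 residual pairs at one state."""
    det = omega_e[0, 0] * omega_e[1, 1] - omega_e[0, 1] * omega_e[1, 0]
    if det <= 0:
        raise ValueError("omega_e is singular or indefinite")
    F = np.column_stack([bundle.Xc @ beta, bundle.Xe @ beta])
    E = bundle.y2 - F - v[bundle.country_index] - u[bundle.study_index]
    W = _inv2(omega_e)
    return bundle.n * (2.0 * _LOG_2PI + float(np.log(det))) + float(
        np.einsum("na,ab,nb->", E, W, E)
    )


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(chains: PosteriorChains, psr_threshold: float = 1.05):
    """Per-parameter trace summaries with split-Rhat and effective sample size.

    Returns a DataFrame indexed by parameter with columns ``mean, sd,
    ess, rhat, flagged``.  Rhat is undefined (NaN) for a constant chain;
    such parameters are flagged for inspection, with ESS capped at the
    number of stored draws.  Requires at least 10 stored draws.
    """
    import arviz as az
    import pandas as pd

    if chains.n_stored < 10:
        raise ValueError("need at least 10 stored draws for diagnostics")
    draws = chains.scalar_draws()
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    n_total = chains.n_chains * chains.n_stored
    for name, arr in draws.items():
        r = float(rhat[name].values)
        e = float(ess[name].values)
        constant = bool(np.allclose(arr, arr.flat[0]))
        if constant:
            r, e = np.nan, float(n_total)
        rows.append(
            {
                "parameter": name,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "ess": min(e, float(n_total)) if np.isfinite(e) else float(n_total),
                "rhat": r,
                "flagged": bool(constant or (np.isfinite(r) and r > psr_threshold)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def mc_se(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of a scalar chain via arviz ESS."""
    import arviz as az

    arr = np.atleast_2d(np.asarray(draws, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        ess = float(az.ess(az.from_dict(posterior={"x": arr}))["x"].values)
    sd = float(arr.std(ddof=1))
    if not np.isfinite(ess) or ess <= 0:
        ess = float(arr.size)
    return sd / np.sqrt(ess)
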