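"""Posterior summaries: VPCs, DIC, fixed-effect tables, shrunken residuals.

The variance partition coefficient (VPC) for response d at the country
level is

    VPC_country,d = σ²_v,d / (σ²_v,d + σ²_u,d + σ²_e,d),

i.e. the share of total residual variance attributable to differences
between countries, with analogous shares for the study and data levels.
Shares are reported as percentages and sum to 100 per response.

The deviance information criterion (DIC) is computed with level-1 focus:
the conditional deviance D(θ) = −2 log p(y | β, v, u, Ω_e) treats the
random effects as parameters, Dbar is its posterior mean, the effective
number of parameters is pD = Dbar − D(θ̄) at the posterior means, and
DIC = Dbar + pD.  Lower is better; differences of 1–2 points are
conventionally regarded as the smallest worth acting on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignBundle
from .gibbs import PosteriorChains, conditional_deviance

__all__ = [
    "compute_vpc",
    "DicResult",
    "compute_dic",
    "FitSummary",
    "summarize_fit",
    "ResidualSet",
    "shrunken_residuals",
]

_LEVELS = ("country", "study", "data")
_RESPONSES = ("cost", "effect")


def _diag_pair(mat: np.ndarray | Any) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape == (2, 2):
        d = np.diag(m)
    elif m.shape == (2,):
        d = m
    else:
        raise ValueError("expected a 2x2 matrix or a length-2 diagonal")
    if np.any(d < 0):
        raise ValueError("variances must be non-negative")
    return d


def compute_vpc(omega_v, omega_u, omega_e) -> pd.DataFrame:
    """Per-response, per-level variance shares as percentages.

    Accepts 2×2 covariance matrices (or bare length-2 diagonals) for the
    country, study, and data levels; only the diagonals enter.  Returns a
    DataFrame indexed by level (country/study/data) with one column per
    response (cost/effect); each column sums to 100.
    """
    d = np.vstack([_diag_pair(omega_v), _diag_pair(omega_u), _diag_pair(omega_e)])
    totals = d.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("total variance must be positive for each response")
    shares = 100.0 * d / totals
    return pd.DataFrame(shares, index=list(_LEVELS), columns=list(_RESPONSES))


@dataclass
class DicResult:
    dic: float
    p_d: float
    dbar: float


def compute_dic(chains: PosteriorChains, bundle: DesignBundle) -> DicResult:
    """DIC with level-1 (conditional-on-random-effects) focus.

    Uses the per-draw conditional deviances stored by the sampler for
    Dbar and plugs the posterior means of (β, v, u, Ω_e) into the same
    deviance for the plug-in term.  Raises if Ω_e at the posterior mean is
    singular.
    """
    dbar = float(chains.deviance.mean())
    beta_bar = chains.pooled(chains.beta).mean(axis=0)
    v_bar = chains.pooled(chains.v).mean(axis=0)
    u_bar = chains.pooled(chains.u).mean(axis=0)
    omega_e_bar = chains.pooled(chains.omega_e).mean(axis=0)
    d_hat = conditional_deviance(bundle, beta_bar, v_bar, u_bar, omega_e_bar)
    p_d = dbar - d_hat
    return DicResult(dic=dbar + p_d, p_d=p_d, dbar=dbar)


def _significance(z: float) -> str:
    p = 2.0 * stats.norm.sf(abs(z))
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


@dataclass
class FitSummary:
    """Posterior summary of one fitted model, shaped like a results table.

    ``fixed_effects`` is indexed by coefficient label (``cost:...`` /
    ``effect:...``) with posterior mean, sd, central 95% interval, and
    two-sided significance stars at the 10/5/1% levels based on the
    posterior mean/SD normal score.  ``omega`` holds the posterior-mean
    covariance matrix per level and ``vpc`` the percentage shares derived
    from those posterior means.
    """

    fixed_effects: pd.DataFrame
    omega: dict[str, np.ndarray]
    vpc: pd.DataFrame
    dic: float
    p_d: float
    dbar: float
    n_data: int
    n_studies: int
    n_countries: int
    structure: str
    metadata: dict = field(default_factory=dict)
    #: pooled posterior draws of each level's covariance, keys 'v','u','e'
    omega_draws: dict[str, np.ndarray] = field(default_factory=dict)
    chains: PosteriorChains | None = None

    def sigma_table(self) -> pd.DataFrame:
        """Level-wise standard deviations (the printed variance components)."""
        rows = {
            level: [float(np.sqrt(self.omega[tag][d, d])) for d in (0, 1)]
            for level, tag in (("country", "v"), ("study", "u"), ("data", "e"))
        }
        return pd.DataFrame(rows, index=list(_RESPONSES)).T

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "n": {
                "data": self.n_data,
                "studies": self.n_studies,
                "countries": self.n_countries,
            },
            "fixed_effects": self.fixed_effects.reset_index().to_dict("records"),
            "sigma": self.sigma_table().to_dict(),
            "vpc": self.vpc.to_dict(),
            "dic": self.dic,
            "p_d": self.p_d,
            "dbar": self.dbar,
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def table(self) -> pd.DataFrame:
        """Results-table view: coefficients, σ per level, VPCs, and DIC."""
        tab = self.fixed_effects[["mean", "sd", "stars"]].copy()
        sig = self.sigma_table()
        extra_rows = {}
        for resp in _RESPONSES:
            for level in _LEVELS:
                extra_rows[f"sigma:{level}:{resp}"] = sig.loc[level, resp]
            for level in _LEVELS:
                extra_rows[f"vpc:{level}:{resp}"] = self.vpc.loc[level, resp]
        extra_rows["dic"] = self.dic
        extra = pd.DataFrame(
            {"mean": list(extra_rows.values()), "sd": np.nan, "stars": ""},
            index=list(extra_rows.keys()),
        )
        return pd.concat([tab, extra])


def summarize_fit(
    chains: PosteriorChains,
    bundle: DesignBundle,
    keep_chains: bool = True,
) -> FitSummary:
    """Summarise posterior chains into a :class:`FitSummary`."""
    beta = chains.pooled(chains.beta)
    fe_rows = []
    for i, name in enumerate(chains.coef_names):
        draws = beta[:, i]
        mean, sd = float(draws.mean()), float(draws.std(ddof=1))
        z = mean / sd if sd > 0 else np.inf * np.sign(mean) if mean else 0.0
        fe_rows.append(
            {
                "coefficient": name,
                "mean": mean,
                "sd": sd,
                "lo95": float(np.quantile(draws, 0.025)),
                "hi95": float(np.quantile(draws, 0.975)),
                "stars": _significance(z),
            }
        )
    fixed = pd.DataFrame(fe_rows).set_index("coefficient")

    omega = {
        "v": chains.pooled(chains.omega_v).mean(axis=0),
        "u": chains.pooled(chains.omega_u).mean(axis=0),
        "e": chains.pooled(chains.omega_e).mean(axis=0),
    }
    vpc = compute_vpc(omega["v"], omega["u"], omega["e"])
    dic = compute_dic(chains, bundle)
    return FitSummary(
        fixed_effects=fixed,
        omega=omega,
        vpc=vpc,
        dic=dic.dic,
        p_d=dic.p_d,
        dbar=dic.dbar,
        n_data=bundle.n,
        n_studies=bundle.n_studies,
        n_countries=bundle.n_countries,
        structure=bundle.structure,
        omega_draws={
            "v": chains.pooled(chains.omega_v),
            "u": chains.pooled(chains.omega_u),
            "e": chains.pooled(chains.omega_e),
        },
        chains=chains if keep_chains else None,
    )


@dataclass
class ResidualSet:
    """Shrunken cluster residuals for caterpillar / forest plots.

    ``table`` is indexed by cluster id with, per response, the posterior
    mean and central 95% interval of the cluster effect, the
    intercept-shifted version (β₀ + effect, the forest-plot quantity), the
    rank by posterior mean ΔC effect, and the normal score matching that
    rank.
    """

    level: str
    table: pd.DataFrame

    def plot(self, response: str = "cost", shifted: bool = False, ax=None):
        """Caterpillar (or forest, when ``shifted``) plot; returns the axes."""
        import matplotlib.pyplot as plt

        prefix = ("shifted_" if shifted else "") + response
        tab = self.table.sort_values(f"{prefix}_mean")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(tab) + 1))
        y = np.arange(len(tab))
        ax.errorbar(
            tab[f"{prefix}_mean"],
            y,
            xerr=np.vstack(
                [
                    tab[f"{prefix}_mean"] - tab[f"{prefix}_lo95"],
                    tab[f"{prefix}_hi95"] - tab[f"{prefix}_mean"],
                ]
            ),
            fmt="o",
            ms=3,
            lw=1,
        )
        if not shifted:
            ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y, tab.index)
        ax.set_xlabel(f"{self.level}-level {'prediction' if shifted else 'residual'} ({response})")
        return ax


def shrunken_residuals(
    chains: PosteriorChains, bundle: DesignBundle, level: str
) -> ResidualSet:
    """Posterior summaries of a level's random effects.

    The posterior mean of a cluster effect is its *shrunken* residual:
    pulled toward zero relative to the cluster's raw mean residual, with
    more shrinkage for clusters contributing fewer estimates.  The shifted
    columns add the corresponding posterior-mean intercept, giving the
    model's prediction for that cluster at average covariate values.
    """
    if level == "country":
        draws, ids = chains.v, chains.country_ids
    elif level == "study":
        draws, ids = chains.u, chains.study_ids
    else:
        raise ValueError(f"unknown residual level {level!r}; use 'country' or 'study'")
    pooled = chains.pooled(draws)  # (T, K, 2)
    beta = chains.pooled(chains.beta)
    intercepts = {}
    for d, resp in enumerate(_RESPONSES):
        label = f"{resp}:intercept"
        intercepts[resp] = (
            float(beta[:, chains.coef_names.index(label)].mean())
            if label in chains.coef_names
            else 0.0
        )
    cols: dict[str, np.ndarray] = {}
    for d, resp in enumerate(_RESPONSES):
        arr = pooled[:, :, d]
        cols[f"{resp}_mean"] = arr.mean(axis=0)
        cols[f"{resp}_lo95"] = np.quantile(arr, 0.025, axis=0)
        cols[f"{resp}_hi95"] = np.quantile(arr, 0.975, axis=0)
        for suffix in ("mean", "lo95", "hi95"):
            cols[f"shifted_{resp}_{suffix}"] = cols[f"{resp}_{suffix}"] + intercepts[resp]
    table = pd.DataFrame(cols, index=list(ids))
    order = table["cost_mean"].rank(method="first").astype(int)
    table["rank"] = order
    table["normal_score"] = stats.norm.ppf((order - 0.375) / (len(table) + 0.25))
    return ResidualSet(level=level, table=table)
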