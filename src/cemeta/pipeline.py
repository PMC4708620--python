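"""End-to-end analysis workflow.

The intended analysis sequence mirrors standard multilevel practice:

1. fit the three structures as variance-components models and compare
   their level-wise variance shares (:func:`compare_structures`);
2. add data- and study-level covariates bottom-up in substantive blocks —
   patient/disease first, then intervention/comparator, then methods —
   keeping a block only when coefficients are significant, plausibly
   signed, and the DIC improves materially (:func:`sequential_build`);
3. probe country-level covariates one at a time against the multivariate
   model, since the number of countries is far too small to support many
   simultaneous country terms (:func:`scan_country_covariates`).

All fits share one composition path (:func:`fit_model`): structural
transform → grand-mean centring → design build → Gibbs sampling →
posterior summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import EvidenceDataset, center_covariates
from .design import (
    STRUCTURES,
    DesignError,
    ModelSpec,
    Priors,
    apply_structure,
    build_design,
    default_priors,
)
from .gibbs import MCMCConfig, run_chain
from .inference import FitSummary, summarize_fit

__all__ = [
    "fit_model",
    "BuildBlock",
    "BuildPlan",
    "BuildTrajectory",
    "sequential_build",
    "scan_country_covariates",
    "compare_structures",
]

logger = logging.getLogger("cemeta")


def fit_model(
    ds: EvidenceDataset,
    spec: ModelSpec,
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
    center: bool = True,
    keep_chains: bool = True,
) -> FitSummary:
    """Fit one bivariate multilevel model end to end.

    Applies the structural transform, centres continuous covariates on
    their grand means over the retained estimates, builds the stacked
    design, runs the Gibbs sampler, and returns the posterior summary.
    Fit metadata (structure, covariates, seed, and any studies dropped by
    the hierarchical transform) is recorded on the summary.
    """
    mcmc = mcmc or MCMCConfig()
    before = set(ds.estimates["study_id"])
    ds2 = apply_structure(ds, spec.structure)
    dropped = sorted(before - set(ds2.estimates["study_id"]))
    if center:
        ds2 = center_covariates(ds2)
    bundle = build_design(ds2, spec)
    if priors is None:
        priors = default_priors(bundle)
    chains = run_chain(bundle, priors, mcmc)
    summary = summarize_fit(chains, bundle, keep_chains=keep_chains)
    summary.metadata.update(
        {
            "structure": spec.structure,
            "covariates_c": list(spec.covariates_c),
            "covariates_e": list(spec.covariates_e),
            "seed": mcmc.seed,
            "n_iter": mcmc.n_iter,
            "burn_in": mcmc.burn_in,
            "n_chains": mcmc.n_chains,
            "dropped_studies": dropped,
        }
    )
    summary.bundle = bundle
    logger.info(
        "fitted %s model: n=%d, studies=%d, countries=%d, DIC=%.1f",
        spec.structure,
        bundle.n,
        bundle.n_studies,
        bundle.n_countries,
        summary.dic,
    )
    return summary


# ---------------------------------------------------------------------------
# sequential bottom-up covariate building


@dataclass
class BuildBlock:
    """One named block of candidate covariates (per response)."""

    name: str
    covariates_c: tuple[str, ...] = ()
    covariates_e: tuple[str, ...] = ()


@dataclass
class BuildPlan:
    """Ordered covariate blocks plus the retention rule.

    A block is kept only if, after dropping its individually failing
    covariates (two-sided significance at ``sig_level`` on the posterior
    normal score, and the expected coefficient sign when one is declared
    in ``expected_signs``, keyed ``"cost:<name>"`` / ``"effect:<name>"``),
    the refitted model lowers DIC by at least ``min_dic_drop``.
    """

    blocks: Sequence[BuildBlock]
    min_dic_drop: float = 2.0
    sig_level: float = 0.10
    expected_signs: Mapping[str, int] = field(default_factory=dict)

    def validate(self) -> "BuildPlan":
        seen: set[str] = set()
        for blk in self.blocks:
            cov = set(blk.covariates_c) | set(blk.covariates_e)
            overlap = seen & cov
            if overlap:
                raise ValueError(f"covariates in multiple blocks: {sorted(overlap)}")
            seen |= cov
        return self


@dataclass
class BuildTrajectory:
    steps: pd.DataFrame  # block, accepted, dic, retained, dropped
    final_spec: ModelSpec
    final_summary: FitSummary


def _passing_covariates(
    summary: FitSummary, names_c, names_e, plan: BuildPlan
) -> tuple[list[str], list[str]]:
    from scipy import stats as _st

    zcrit = _st.norm.ppf(1 - plan.sig_level / 2)
    keep_c, keep_e = [], []
    fe = summary.fixed_effects
    for resp, names, keep in (("cost", names_c, keep_c), ("effect", names_e, keep_e)):
        for name in names:
            labels = [
                lab
                for lab in fe.index
                if lab == f"{resp}:{name}" or lab.startswith(f"{resp}:{name}[")
            ]
            if not labels:
                continue
            z = (fe.loc[labels, "mean"] / fe.loc[labels, "sd"]).abs()
            significant = bool((z >= zcrit).any())
            sign_ok = True
            want = plan.expected_signs.get(f"{resp}:{name}")
            if want is not None:
                sign_ok = bool(
                    (np.sign(fe.loc[labels, "mean"]) == np.sign(want)).all()
                )
            if significant and sign_ok:
                keep.append(name)
    return keep_c, keep_e


def sequential_build(
    ds: EvidenceDataset,
    spec0: ModelSpec,
    plan: BuildPlan,
    mcmc: MCMCConfig | None = None,
) -> BuildTrajectory:
    """Bottom-up covariate building with DIC-guided block retention.

    Starting from ``spec0`` (typically a variance-components model), each
    block is added in order; covariates failing the significance/sign
    screen are dropped, the surviving set is refitted, and the step is
    accepted only when DIC falls by at least the plan's threshold — so the
    recorded trajectory of accepted models has non-increasing DIC.  If no
    block survives, the baseline model is returned (with a warning in the
    step log).
    """
    plan.validate()
    mcmc = mcmc or MCMCConfig()
    current_spec = spec0
    current = fit_model(ds, current_spec, mcmc=mcmc)
    rows = [
        {
            "block": "<baseline>",
            "accepted": True,
            "dic": current.dic,
            "retained": [],
            "dropped": [],
        }
    ]
    for blk in plan.blocks:
        cand_spec = current_spec.with_added(blk.covariates_c, blk.covariates_e)
        cand = fit_model(ds, cand_spec, mcmc=mcmc)
        keep_c, keep_e = _passing_covariates(
            cand, blk.covariates_c, blk.covariates_e, plan
        )
        dropped = sorted(
            (set(blk.covariates_c) - set(keep_c))
            | (set(blk.covariates_e) - set(keep_e))
        )
        if not keep_c and not keep_e:
            rows.append(
                {
                    "block": blk.name,
                    "accepted": False,
                    "dic": cand.dic,
                    "retained": [],
                    "dropped": dropped,
                }
            )
            continue
        if dropped:
            kept_spec = current_spec.with_added(keep_c, keep_e)
            kept = fit_model(ds, kept_spec, mcmc=mcmc)
        else:
            kept_spec, kept = cand_spec, cand
        if kept.dic <= current.dic - plan.min_dic_drop:
            current_spec, current = kept_spec, kept
            rows.append(
                {
                    "block": blk.name,
                    "accepted": True,
                    "dic": kept.dic,
                    "retained": sorted(set(keep_c) | set(keep_e)),
                    "dropped": dropped,
                }
            )
        else:
            rows.append(
                {
                    "block": blk.name,
                    "accepted": False,
                    "dic": kept.dic,
                    "retained": [],
                    "dropped": sorted(set(blk.covariates_c) | set(blk.covariates_e)),
                }
            )
    if len([r for r in rows if r["accepted"]]) == 1:
        logger.warning("no covariate block survived; returning the baseline model")
    return BuildTrajectory(
        steps=pd.DataFrame(rows), final_spec=current_spec, final_summary=current
    )


# ---------------------------------------------------------------------------
# country-covariate scan


def scan_country_covariates(
    ds: EvidenceDataset,
    base_spec: ModelSpec,
    candidates: Sequence[str],
    mcmc: MCMCConfig | None = None,
    responses: tuple[str, ...] = ("cost", "effect"),
    base_fit: FitSummary | None = None,
) -> pd.DataFrame:
    """Test country-level covariates one at a time against a base model.

    Each candidate is added (to the responses requested) on top of
    ``base_spec`` and refitted with the same seed; the returned table has
    one row per candidate with the coefficient, posterior SD, and
    significance stars per response, and the DIC change against the base
    fit.  A candidate that is constant across the in-model countries, or
    missing for any of them, is flagged and not fitted.
    """
    mcmc = mcmc or MCMCConfig()
    if base_fit is None:
        base_fit = fit_model(ds, base_spec, mcmc=mcmc)
    ds_struct = apply_structure(ds, base_spec.structure)
    rows = []
    for name in candidates:
        row: dict = {"covariate": name, "flagged": False, "note": ""}
        try:
            vals = ds_struct.covariate_column(name)
        except Exception as exc:  # unknown covariate
            row.update(flagged=True, note=str(exc))
            rows.append(row)
            continue
        arr = pd.to_numeric(vals, errors="coerce")
        if arr.isna().any():
            bad = sorted(
                ds_struct.estimates.loc[arr.isna().to_numpy(), "country_code"].unique()
            )
            row.update(flagged=True, note=f"missing for countries {bad}")
            rows.append(row)
            continue
        if float(np.var(arr.to_numpy())) == 0.0:
            row.update(flagged=True, note="constant across in-model estimates")
            rows.append(row)
            continue
        spec = base_spec.with_added(
            (name,) if "cost" in responses else (),
            (name,) if "effect" in responses else (),
        )
        fit = fit_model(ds, spec, mcmc=mcmc)
        for resp in ("cost", "effect"):
            label = f"{resp}:{name}"
            if label in fit.fixed_effects.index:
                fe = fit.fixed_effects.loc[label]
                row[f"coef_{resp}"] = float(fe["mean"])
                row[f"sd_{resp}"] = float(fe["sd"])
                row[f"stars_{resp}"] = fe["stars"]
        row["delta_dic"] = float(fit.dic - base_fit.dic)
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# structure comparison


def compare_structures(
    ds: EvidenceDataset,
    mcmc: MCMCConfig | None = None,
    priors: Priors | None = None,
    spec_template: ModelSpec | None = None,
) -> pd.DataFrame:
    """Fit all three structures as variance-components models.

    Returns one row per structure with group counts, intercepts,
    level-wise standard deviations, VPC percentages, and DIC.  The
    hierarchical row's DIC is marked non-comparable because that model is
    fitted to the subset of single-country studies only.  The returned
    frame carries the fitted summaries in ``.attrs['fits']``.
    """
    mcmc = mcmc or MCMCConfig()
    template = spec_template or ModelSpec()
    rows = []
    fits: dict[str, FitSummary] = {}
    for structure in STRUCTURES:
        spec = ModelSpec(
            structure=structure,
            covariates_c=template.covariates_c,
            covariates_e=template.covariates_e,
        )
        fit = fit_model(ds, spec, priors=priors, mcmc=mcmc)
        fits[structure] = fit
        sig = fit.sigma_table()
        pooled = structure == "hybrid" and "MULTI" in fit.chains.country_ids
        row = {
            "structure": structure,
            "n_countries": fit.n_countries - (1 if pooled else 0),
            "pooled_group": pooled,
            "n_studies": fit.n_studies,
            "n_data": fit.n_data,
            "dic": fit.dic,
            "dic_comparable": structure != "hierarchical",
        }
        for resp in ("cost", "effect"):
            label = f"{resp}:intercept"
            if label in fit.fixed_effects.index:
                row[f"intercept_{resp}"] = float(
                    fit.fixed_effects.loc[label, "mean"]
                )
                row[f"intercept_se_{resp}"] = float(fit.fixed_effects.loc[label, "sd"])
            for level in ("country", "study", "data"):
                row[f"sigma_{level}_{resp}"] = float(sig.loc[level, resp])
                row[f"vpc_{level}_{resp}"] = float(fit.vpc.loc[level, resp])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("structure")
    out.attrs["fits"] = fits
    return out
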