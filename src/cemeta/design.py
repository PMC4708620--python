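"""Model structures, stacked bivariate design matrices, and default priors.

Three random-intercept structures are supported for estimates grouped in
studies and countries:

* ``cross_classified`` — studies and countries are crossed classifications
  of the estimates; multinational studies keep their per-country blocks.
* ``hierarchical`` — strict nesting (estimate ⊂ study ⊂ country); data
  from multinational studies are removed.
* ``hybrid`` — all data retained, but every estimate from a multinational
  study is reassigned to one pooled country-level group, so multinational
  information contributes at the data and study levels without entering
  the between-country comparison.

The bivariate response is implemented by stacking: each estimate
contributes a ΔC row and a ΔE row, with response-indicator columns so the
two equations can carry different covariates while their level-1 errors
remain correlated.  Column order is response-major (all ΔC coefficients,
then all ΔE coefficients), each response ordered intercept-first then as
listed in the model spec, with categorical covariates expanded in sorted
level order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    POOLED_COUNTRY_LABEL,
    EncodingPlan,
    EvidenceDataset,
    SchemaError,
    encode_categoricals,
)

__all__ = [
    "STRUCTURES",
    "ModelSpec",
    "DesignBundle",
    "Priors",
    "DesignError",
    "apply_structure",
    "build_design",
    "default_priors",
]

STRUCTURES = ("hierarchical", "hybrid", "cross_classified")
RESPONSES = ("cost", "effect")


class DesignError(ValueError):
    """The model specification cannot be realised on this dataset."""


@dataclass
class ModelSpec:
    """Choice of structure and per-response covariate lists.

    Covariates are named by their full column names (``d_``/``s_``/``c_``
    prefixes) and may sit at any level; ``covariates_c`` enters the ΔC
    equation and ``covariates_e`` the ΔE equation.  Intercepts can be
    switched off per response (used e.g. to pin a response's mean at zero
    in oracle checks).
    """

    structure: str = "cross_classified"
    covariates_c: tuple[str, ...] = ()
    covariates_e: tuple[str, ...] = ()
    include_intercept_c: bool = True
    include_intercept_e: bool = True

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise DesignError(f"unknown structure {self.structure!r}")
        self.covariates_c = tuple(self.covariates_c)
        self.covariates_e = tuple(self.covariates_e)

    def with_added(self, extra_c=(), extra_e=()) -> "ModelSpec":
        return ModelSpec(
            structure=self.structure,
            covariates_c=self.covariates_c + tuple(extra_c),
            covariates_e=self.covariates_e + tuple(extra_e),
            include_intercept_c=self.include_intercept_c,
            include_intercept_e=self.include_intercept_e,
        )


def apply_structure(ds: EvidenceDataset, structure: str) -> EvidenceDataset:
    """Realise a model structure on the dataset.

    ``hierarchical`` drops all estimates (and study rows) from
    multinational studies and keeps only referenced countries;
    ``hybrid`` rewrites the country code of every multinational-study
    estimate to the pooled label and records the pooled members;
    ``cross_classified`` returns an unchanged copy.
    """
    if structure not in STRUCTURES:
        raise DesignError(f"unknown structure {structure!r}")
    out = ds.copy()
    out.structure_applied = structure
    multi = set(out.multinational_studies())
    if structure == "cross_classified" or not multi:
        return out
    if structure == "hierarchical":
        out.estimates = out.estimates[~out.estimates["study_id"].isin(multi)].reset_index(
            drop=True
        )
        out.studies = out.studies[~out.studies["study_id"].isin(multi)].reset_index(
            drop=True
        )
        used = set(out.estimates["country_code"])
        out.countries = out.countries[
            out.countries["country_code"].isin(used)
        ].reset_index(drop=True)
        return out
    # hybrid
    mask = out.estimates["study_id"].isin(multi)
    members = tuple(sorted(set(out.estimates.loc[mask, "country_code"])))
    out.estimates = out.estimates.copy()
    out.estimates.loc[mask, "country_code"] = POOLED_COUNTRY_LABEL
    # keep pooled-member rows: they back the member-mean fill of country
    # covariates for the pooled group
    used = (set(out.estimates["country_code"]) - {POOLED_COUNTRY_LABEL}) | set(members)
    out.countries = out.countries[
        out.countries["country_code"].isin(used)
    ].reset_index(drop=True)
    out.pooled_members = members
    return out


@dataclass
class DesignBundle:
    """Stacked design matrices and cluster index maps for one model.

    ``y2`` is the (N, 2) response array (ΔC, ΔE); ``Xc`` and ``Xe`` are
    (N, p) matrices holding each coefficient column's value on its own
    response's rows and zeros elsewhere, so the stacked (2N, p) design is
    ``vstack([Xc, Xe])`` against ``concat([ΔC, ΔE])``.  ``coef_names``
    labels the p columns as ``"cost:..."`` / ``"effect:..."``.
    """

    y2: np.ndarray
    Xc: np.ndarray
    Xe: np.ndarray
    coef_names: tuple[str, ...]
    study_index: np.ndarray
    country_index: np.ndarray
    study_ids: tuple[str, ...]
    country_ids: tuple[str, ...]
    estimate_ids: tuple[str, ...]
    structure: str

    @property
    def n(self) -> int:
        return self.y2.shape[0]

    @property
    def p(self) -> int:
        return self.Xc.shape[1]

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def n_countries(self) -> int:
        return len(self.country_ids)

    @property
    def y(self) -> np.ndarray:
        """Stacked (2N,) response: all ΔC rows then all ΔE rows."""
        return np.concatenate([self.y2[:, 0], self.y2[:, 1]])

    @property
    def X(self) -> np.ndarray:
        """Stacked (2N, p) fixed-effects design matching :attr:`y`."""
        return np.vstack([self.Xc, self.Xe])

    def study_to_country(self) -> dict[int, int] | None:
        """The j→k map when studies nest in countries, else None."""
        mapping: dict[int, int] = {}
        for j, k in zip(self.study_index, self.country_index):
            if j in mapping and mapping[j] != k:
                return None
            mapping[int(j)] = int(k)
        return mapping


def _resolve_columns(
    ds: EvidenceDataset, names: tuple[str, ...], plan: EncodingPlan
) -> tuple[list[str], pd.DataFrame]:
    """Expand covariate names into numeric columns aligned to estimates."""
    cols: list[str] = []
    data: dict[str, np.ndarray] = {}
    for name in names:
        meta = ds._require_meta(name)
        series = ds.covariate_column(name)
        if meta.kind == "continuous":
            vals = pd.to_numeric(series, errors="coerce")
            _check_missing(ds, name, vals.isna())
            cols.append(name)
            data[name] = vals.to_numpy(dtype=float)
        else:
            block = plan.expand(name, series)
            _check_missing(ds, name, block.isna().any(axis=1))
            for col in block.columns:
                cols.append(col)
                data[col] = block[col].to_numpy(dtype=float)
    return cols, pd.DataFrame(data)


def _check_missing(ds: EvidenceDataset, name: str, missing: pd.Series) -> None:
    if missing.any():
        meta = ds.covariate_meta[name]
        key = {"data": "estimate_id", "study": "study_id", "country": "country_code"}[
            meta.level
        ]
        bad = sorted(ds.estimates.loc[missing.to_numpy(), key].unique())
        raise DesignError(
            f"covariate {name!r} has missing values for {meta.level}-level "
            f"cluster(s) {bad}"
        )


def build_design(ds: EvidenceDataset, spec: ModelSpec) -> DesignBundle:
    """Build the stacked bivariate design for one model specification.

    Assumes continuous covariates are already centred and uses the
    dataset's covariate metadata for categorical references.  The
    hierarchical structure requires every study to report for exactly one
    country.
    """
    if spec.structure == "hierarchical":
        per_study = ds.estimates.groupby("study_id")["country_code"].nunique()
        offenders = per_study[per_study > 1].index.tolist()
        if offenders:
            raise DesignError(
                f"hierarchical structure requires one country per study; "
                f"offending studies: {offenders}"
            )

    plan = encode_categoricals(ds)
    n = len(ds.estimates)
    y2 = ds.estimates[["delta_c", "delta_e"]].to_numpy(dtype=float)

    names_c, block_c = _resolve_columns(ds, spec.covariates_c, plan)
    names_e, block_e = _resolve_columns(ds, spec.covariates_e, plan)

    cols_c = (["intercept"] if spec.include_intercept_c else []) + names_c
    cols_e = (["intercept"] if spec.include_intercept_e else []) + names_e
    p = len(cols_c) + len(cols_e)
    Xc = np.zeros((n, p))
    Xe = np.zeros((n, p))
    coef_names = []
    col = 0
    for name in cols_c:
        coef_names.append(f"cost:{name}")
        Xc[:, col] = 1.0 if name == "intercept" else block_c[name].to_numpy()
        col += 1
    for name in cols_e:
        coef_names.append(f"effect:{name}")
        Xe[:, col] = 1.0 if name == "intercept" else block_e[name].to_numpy()
        col += 1

    study_ids = tuple(sorted(ds.estimates["study_id"].unique()))
    country_ids = tuple(sorted(ds.estimates["country_code"].unique()))
    study_lut = {s: i for i, s in enumerate(study_ids)}
    country_lut = {c: i for i, c in enumerate(country_ids)}
    return DesignBundle(
        y2=y2,
        Xc=Xc,
        Xe=Xe,
        coef_names=tuple(coef_names),
        study_index=ds.estimates["study_id"].map(study_lut).to_numpy(dtype=int),
        country_index=ds.estimates["country_code"].map(country_lut).to_numpy(dtype=int),
        study_ids=study_ids,
        country_ids=country_ids,
        estimate_ids=tuple(ds.estimates["estimate_id"]),
        structure=spec.structure,
    )


# ---------------------------------------------------------------------------
# priors


@dataclass
class Priors:
    """Diffuse-normal coefficients and inverse-Wishart covariance priors.

    ``beta_precision`` may be 0 for an improper flat coefficient prior.
    ``pin_omega_*`` fixes a level's covariance matrix instead of sampling
    it; pinning the country or study matrix to exact zero removes that
    level's random effects entirely.
    """

    beta_mean: np.ndarray
    beta_precision: np.ndarray  # per-coefficient prior precision (diagonal)
    df_v: float = 3.0
    df_u: float = 3.0
    df_e: float = 3.0
    scale_v: np.ndarray = field(default_factory=lambda: np.eye(2))
    scale_u: np.ndarray = field(default_factory=lambda: np.eye(2))
    scale_e: np.ndarray = field(default_factory=lambda: np.eye(2))
    pin_omega_v: np.ndarray | None = None
    pin_omega_u: np.ndarray | None = None
    pin_omega_e: np.ndarray | None = None

    def validate(self) -> "Priors":
        for label, df, scale in (
            ("v", self.df_v, self.scale_v),
            ("u", self.df_u, self.scale_u),
            ("e", self.df_e, self.scale_e),
        ):
            if df <= 1.0:  # dimension 2: need df > p - 1
                raise ValueError(f"wishart df for level {label} must exceed 1")
            s = np.asarray(scale, dtype=float)
            if s.shape != (2, 2) or np.linalg.eigvalsh(s).min() <= 0:
                raise ValueError(f"wishart scale for level {label} must be 2x2 PD")
        if np.any(np.asarray(self.beta_precision) < 0):
            raise ValueError("beta_precision must be non-negative")
        return self


def _cluster_mean_cov(resid: np.ndarray, index: np.ndarray) -> np.ndarray | None:
    """Covariance of per-cluster mean residuals; None when < 3 clusters."""
    k = index.max() + 1 if len(index) else 0
    if k < 3:
        return None
    sums = np.zeros((k, 2))
    np.add.at(sums, index, resid)
    counts = np.bincount(index, minlength=k).astype(float)
    means = sums / counts[:, None]
    return np.cov(means.T)


def _pd_or_none(mat: np.ndarray | None) -> np.ndarray | None:
    if mat is None:
        return None
    mat = np.asarray(mat, dtype=float)
    if not np.all(np.isfinite(mat)) or np.linalg.eigvalsh(mat).min() <= 0:
        return None
    return mat


def default_priors(bundle: DesignBundle, warn: bool = True) -> Priors:
    """Diffuse coefficient priors plus moment-based Wishart scales.

    Coefficients get independent normal priors with mean 0 and variance
    10^6 × the sample variance of their response, i.e. precision 1e-6 in
    units of the response scale.  (An absolute precision cannot be diffuse
    for both responses at once: incremental costs in GBP and incremental
    effects in life-years differ in scale by four orders of magnitude, and
    a fixed prior variance of 10^6 would actively shrink cost
    coefficients.)  Each
    level's Wishart scale is df × an ANOVA-type moment estimate of that
    level's residual covariance (covariance of per-cluster mean OLS
    residuals at the country and study levels; covariance of
    within-study-centred residuals at the data level), replaced by the
    identity when the estimate is unavailable or not positive definite —
    this moment step plays the role of a frequentist warm start for the
    sampler's covariance priors.
    """
    import warnings

    p = bundle.p
    beta_hat, *_ = np.linalg.lstsq(bundle.X, bundle.y, rcond=None)
    fitted = np.column_stack([bundle.Xc @ beta_hat, bundle.Xe @ beta_hat])
    resid = bundle.y2 - fitted

    est_v = _pd_or_none(_cluster_mean_cov(resid, bundle.country_index))
    est_u = _pd_or_none(_cluster_mean_cov(resid, bundle.study_index))
    j = bundle.study_index
    k = int(j.max()) + 1
    sums = np.zeros((k, 2))
    np.add.at(sums, j, resid)
    counts = np.bincount(j, minlength=k).astype(float)
    within = resid - (sums / counts[:, None])[j]
    est_e = _pd_or_none(np.cov(within.T)) if bundle.n >= 3 else None

    resp_var = np.maximum(bundle.y2.var(axis=0, ddof=1), 1e-12)
    prec = np.array(
        [
            1e-6 / resp_var[0 if name.startswith("cost:") else 1]
            for name in bundle.coef_names
        ]
    )
    pri = Priors(
        beta_mean=np.zeros(p),
        beta_precision=prec,
    )
    for label, est, df_attr, scale_attr in (
        ("country", est_v, "df_v", "scale_v"),
        ("study", est_u, "df_u", "scale_u"),
        ("data", est_e, "df_e", "scale_e"),
    ):
        df = getattr(pri, df_attr)
        if est is None:
            if warn:
                warnings.warn(
                    f"{label}-level moment estimate unavailable or not PD; "
                    f"using identity Wishart scale",
                    stacklevel=2,
                )
            setattr(pri, scale_attr, np.eye(2))
        else:
            setattr(pri, scale_attr, df * est)
    return pri.validate()
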