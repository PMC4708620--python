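"""Three-table evidence base: loading, validation, and preprocessing.

A cost-effectiveness evidence base links three tables:

* **estimates** — one row per published (ΔC, ΔE) pair, i.e. a base-case,
  subgroup, or sensitivity analysis from one study targeting one country.
  Data-level covariate columns are prefixed ``d_``.
* **studies** — one row per publication, with the set of countries it
  reports for (a study is *multinational* iff it reports for more than
  one).  Study-level covariate columns are prefixed ``s_``.
* **countries** — one row per country, with national statistics as
  covariates.  Columns are prefixed ``c_``.

ΔC is expressed in a common currency and price year (GBP, 2010) before the
data enter any model; :func:`standardize_cost` implements the purchasing
power parity / GDP-deflator conversion.  Continuous covariates are
grand-mean centred over estimates so model intercepts are predictions at
average covariate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CovariateMeta",
    "EvidenceDataset",
    "EncodingPlan",
    "load_dataset",
    "write_dataset",
    "standardize_cost",
    "center_covariates",
    "encode_categoricals",
    "POOLED_COUNTRY_LABEL",
]

#: Label used for the pooled country-level group that absorbs all
#: multinational-study data under the hybrid hierarchical structure.
POOLED_COUNTRY_LABEL = "MULTI"

_LEVELS = ("data", "study", "country")
_PREFIX_TO_LEVEL = {"d_": "data", "s_": "study", "c_": "country"}


class SchemaError(ValueError):
    """A table violates the evidence-base schema (names the offending cell)."""


@dataclass
class CovariateMeta:
    """Per-covariate metadata.

    Parameters
    ----------
    name : str
        Column name including its level prefix (``d_``/``s_``/``c_``).
    level : {'data', 'study', 'country'}
    kind : {'continuous', 'categorical'}
    reference : str, optional
        Reference level for categorical covariates (gets no indicator).
    center : bool
        Whether the covariate is grand-mean centred before modelling.
        Only meaningful for continuous covariates.
    centering_constant : float, optional
        The grand mean subtracted by :func:`center_covariates`; recorded so
        intercepts can be mapped back to the raw covariate scale.
    """

    name: str
    level: str
    kind: str
    reference: str | None = None
    center: bool = True
    centering_constant: float | None = None

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise SchemaError(f"covariate {self.name!r}: unknown level {self.level!r}")
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"covariate {self.name!r}: unknown type {self.kind!r}")


@dataclass
class EvidenceDataset:
    """Linked estimate / study / country tables plus covariate metadata.

    ``estimates`` has columns ``estimate_id, study_id, country_code,
    delta_c, delta_e, is_base_case`` plus ``d_*`` covariates; ``studies``
    has ``study_id, year, countries`` (a list of codes) plus ``s_*``;
    ``countries`` has ``country_code`` plus ``c_*``.
    """

    estimates: pd.DataFrame
    studies: pd.DataFrame
    countries: pd.DataFrame
    covariate_meta: dict[str, CovariateMeta] = field(default_factory=dict)
    #: which structural transform produced this dataset, if any
    structure_applied: str | None = None
    #: original member countries of the pooled group, when one exists
    pooled_members: tuple[str, ...] = ()

    # -- basic accessors -------------------------------------------------
    @property
    def n_estimates(self) -> int:
        return len(self.estimates)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_countries(self) -> int:
        """Number of distinct country groups actually referenced by estimates."""
        return self.estimates["country_code"].nunique()

    def multinational_studies(self) -> list[str]:
        """Study ids reporting estimates for more than one country."""
        return [
            row.study_id
            for row in self.studies.itertuples()
            if len(row.countries) > 1
        ]

    def copy(self) -> "EvidenceDataset":
        return EvidenceDataset(
            estimates=self.estimates.copy(),
            studies=self.studies.copy(),
            countries=self.countries.copy(),
            covariate_meta={k: replace(v) for k, v in self.covariate_meta.items()},
            structure_applied=self.structure_applied,
            pooled_members=self.pooled_members,
        )

    # -- covariate access ------------------------------------------------
    def covariate_column(self, name: str, pooled_fill: str = "member_mean") -> pd.Series:
        """Covariate values aligned to the estimates table (length N).

        Study- and country-level covariates are broadcast to the estimates
        that belong to each cluster.  For a pooled country group (hybrid
        structure) a continuous country covariate is, by default, filled
        with the unweighted mean over the group's member countries;
        ``pooled_fill='nan'`` leaves it missing instead.
        """
        meta = self._require_meta(name)
        if meta.level == "data":
            return self.estimates[name].reset_index(drop=True)
        if meta.level == "study":
            lut = self.studies.set_index("study_id")[name]
            return (
                self.estimates["study_id"].map(lut).reset_index(drop=True).rename(name)
            )
        lut = self.countries.set_index("country_code")[name]
        out = self.estimates["country_code"].map(lut).reset_index(drop=True).rename(name)
        if (
            pooled_fill == "member_mean"
            and meta.kind == "continuous"
            and self.pooled_members
            and (self.estimates["country_code"] == POOLED_COUNTRY_LABEL).any()
        ):
            members = [m for m in self.pooled_members if m in lut.index]
            if members:
                fill = float(lut.loc[members].mean())
                mask = (
                    self.estimates["country_code"].reset_index(drop=True)
                    == POOLED_COUNTRY_LABEL
                )
                out[mask] = fill
        return out

    def _require_meta(self, name: str) -> CovariateMeta:
        if name not in self.covariate_meta:
            raise SchemaError(f"unknown covariate {name!r}")
        return self.covariate_meta[name]

    # -- validation ------------------------------------------------------
    def validate(self) -> "EvidenceDataset":
        """Check referential integrity and the type invariants; return self."""
        est, stu, cty = self.estimates, self.studies, self.countries
        for col in ("estimate_id", "study_id", "country_code", "delta_c", "delta_e"):
            if col not in est.columns:
                raise SchemaError(f"estimates table: missing column {col!r}")
        dup = est["estimate_id"][est["estimate_id"].duplicated()].tolist()
        if dup:
            raise SchemaError(f"duplicate estimate_id: {sorted(set(dup))}")
        dup = stu["study_id"][stu["study_id"].duplicated()].tolist()
        if dup:
            raise SchemaError(f"duplicate study_id: {sorted(set(dup))}")
        dup = cty["country_code"][cty["country_code"].duplicated()].tolist()
        if dup:
            raise SchemaError(f"duplicate country_code: {sorted(set(dup))}")

        for col in ("delta_c", "delta_e"):
            vals = pd.to_numeric(est[col], errors="coerce")
            bad = est.loc[~np.isfinite(vals), "estimate_id"].tolist()
            if bad:
                raise SchemaError(f"non-finite {col} for estimates {bad}")

        known_studies = set(stu["study_id"])
        missing = sorted(set(est["study_id"]) - known_studies)
        if missing:
            raise SchemaError(f"estimates reference unknown studies {missing}")
        known_countries = set(cty["country_code"]) | {POOLED_COUNTRY_LABEL}
        missing = sorted(set(est["country_code"]) - known_countries)
        if missing:
            raise SchemaError(f"estimates reference unknown countries {missing}")

        empty = [r.study_id for r in stu.itertuples() if len(r.countries) == 0]
        if empty:
            raise SchemaError(f"studies with empty country set: {empty}")
        # each estimate's target country must be declared by its study
        declared = {r.study_id: set(r.countries) for r in stu.itertuples()}
        for row in est.itertuples():
            if row.country_code == POOLED_COUNTRY_LABEL:
                continue
            if row.country_code not in declared[row.study_id]:
                raise SchemaError(
                    f"estimate {row.estimate_id}: country {row.country_code!r} "
                    f"not declared by study {row.study_id}"
                )
        for name, meta in self.covariate_meta.items():
            table = {"data": est, "study": stu, "country": cty}[meta.level]
            if name not in table.columns:
                raise SchemaError(
                    f"covariate {name!r} declared at level {meta.level!r} "
                    f"but absent from that table"
                )
        return self


# ---------------------------------------------------------------------------
# loading / writing


def _infer_meta(
    estimates: pd.DataFrame, studies: pd.DataFrame, countries: pd.DataFrame
) -> dict[str, CovariateMeta]:
    meta: dict[str, CovariateMeta] = {}
    for table in (estimates, studies, countries):
        for col in table.columns:
            prefix = col[:2]
            if prefix not in _PREFIX_TO_LEVEL:
                continue
            level = _PREFIX_TO_LEVEL[prefix]
            if pd.api.types.is_numeric_dtype(table[col]):
                meta[col] = CovariateMeta(col, level, "continuous")
            else:
                ref = sorted(table[col].dropna().astype(str).unique())
                meta[col] = CovariateMeta(
                    col, level, "categorical", reference=ref[0] if ref else None,
                    center=False,
                )
    return meta


def _meta_from_yaml(path: Path) -> dict[str, CovariateMeta]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    meta = {}
    for name, entry in raw.items():
        meta[name] = CovariateMeta(
            name=name,
            level=entry["level"],
            kind=entry.get("type", "continuous"),
            reference=entry.get("reference"),
            center=bool(entry.get("center", entry.get("type", "continuous") == "continuous")),
            centering_constant=entry.get("centering_constant"),
        )
    return meta


def load_dataset(
    estimates_path: str | Path,
    studies_path: str | Path,
    countries_path: str | Path,
    meta_path: str | Path | None = None,
) -> EvidenceDataset:
    """Read and validate the three-table evidence base from CSV files.

    ``meta_path`` points at an optional YAML file mapping covariate columns
    to ``{level, type, reference, center}``; columns not listed are
    inferred from their prefix and dtype.  Row order is preserved.
    """
    est = pd.read_csv(estimates_path)
    stu = pd.read_csv(studies_path)
    cty = pd.read_csv(countries_path)
    if "countries" not in stu.columns:
        raise SchemaError("studies table: missing column 'countries'")
    stu = stu.copy()
    stu["countries"] = [
        tuple(str(c).split(";")) if not pd.isna(c) else ()
        for c in stu["countries"]
    ]
    if "is_base_case" in est.columns:
        est["is_base_case"] = est["is_base_case"].astype(bool)
    meta = _infer_meta(est, stu, cty)
    if meta_path is not None:
        meta.update(_meta_from_yaml(Path(meta_path)))
    ds = EvidenceDataset(est, stu, cty, meta)
    return ds.validate()


def write_dataset(ds: EvidenceDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three CSVs plus ``covariate_meta.yaml``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "estimates": out / "estimates.csv",
        "studies": out / "studies.csv",
        "countries": out / "countries.csv",
        "meta": out / "covariate_meta.yaml",
    }
    ds.estimates.to_csv(paths["estimates"], index=False)
    stu = ds.studies.copy()
    stu["countries"] = [";".join(c) for c in stu["countries"]]
    stu.to_csv(paths["studies"], index=False)
    ds.countries.to_csv(paths["countries"], index=False)
    meta_doc = {
        name: {
            "level": m.level,
            "type": m.kind,
            **({"reference": m.reference} if m.reference is not None else {}),
            "center": m.center,
            **(
                {"centering_constant": float(m.centering_constant)}
                if m.centering_constant is not None
                else {}
            ),
        }
        for name, m in ds.covariate_meta.items()
    }
    paths["meta"].write_text(yaml.safe_dump(meta_doc, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# currency standardization


class CurrencyLookupError(KeyError):
    """A (currency, year) pair is absent from a conversion table."""


def standardize_cost(
    amount: float,
    currency: str,
    price_year: int,
    ppp: Mapping[str, float],
    deflator: Mapping[tuple[str, int], float],
    euro_rates: Mapping[str, float] | None = None,
    country: str | None = None,
    target_year: int = 2010,
) -> float:
    """Convert a cost to GBP at the target price level (2010 by default).

    The conversion first maps legacy Eurozone currencies to EUR at their
    irrevocable fixed rates (``euro_rates``, in legacy units per EUR), then
    inflates from ``price_year`` to ``target_year`` with a GDP-deflator
    index, and finally converts to GBP with a purchasing-power-parity
    factor (``ppp``, in currency units per GBP)::

        gbp = amount * (deflator[target_year] / deflator[price_year]) / ppp

    ``deflator`` is keyed by ``(code, year)`` where ``code`` is ``country``
    when given, else the (post-Euro-conversion) currency code — deflators
    are national statistics, so pass ``country`` for Eurozone members.
    """
    cur = currency
    if euro_rates and cur in euro_rates:
        amount = amount / euro_rates[cur]
        cur = "EUR"
    code = country if country is not None else cur
    try:
        d_from = deflator[(code, price_year)]
        d_to = deflator[(code, target_year)]
    except KeyError as exc:
        raise CurrencyLookupError(
            f"no GDP deflator for ({code!r}, {exc.args[0][1] if isinstance(exc.args[0], tuple) else exc.args[0]})"
        ) from exc
    try:
        rate = ppp[cur]
    except KeyError as exc:
        raise CurrencyLookupError(f"no PPP rate for currency {cur!r}") from exc
    return amount * (d_to / d_from) / rate


# ---------------------------------------------------------------------------
# centering and categorical encoding


def center_covariates(ds: EvidenceDataset) -> EvidenceDataset:
    """Grand-mean centre every continuous covariate flagged ``center``.

    The mean is taken over *estimates* (study- and country-level values are
    broadcast to their estimates first), so after centring each covariate
    has estimate-weighted mean zero and intercepts are interpretable as
    predictions for the average reported analysis.  Centering constants are
    accumulated in the covariate metadata; applying the function twice is a
    no-op in value terms.
    """
    out = ds.copy()
    tables = {"data": out.estimates, "study": out.studies, "country": out.countries}
    for name, meta in out.covariate_meta.items():
        if meta.kind == "categorical":
            if meta.center:
                raise TypeError(f"cannot centre categorical covariate {name!r}")
            continue
        if not meta.center:
            continue
        col = out.covariate_column(name, pooled_fill="nan")
        mean = float(np.nanmean(col.to_numpy(dtype=float)))
        if math.isnan(mean):
            continue
        table = tables[meta.level]
        table[name] = table[name].astype(float) - mean
        meta.centering_constant = (meta.centering_constant or 0.0) + mean
    return out


@dataclass
class EncodingPlan:
    """Indicator expansion plan for categorical covariates.

    ``columns`` maps each categorical covariate to the ordered list of
    non-reference levels; indicator columns are named ``name[level]``.
    """

    columns: dict[str, list[str]]
    references: dict[str, str]

    def indicator_names(self, name: str) -> list[str]:
        return [f"{name}[{lvl}]" for lvl in self.columns[name]]

    def expand(self, name: str, values: pd.Series) -> pd.DataFrame:
        """Expand one covariate column into its 0/1 indicator block."""
        levels = self.columns[name]
        known = set(levels) | {self.references[name]}
        seen = set(values.dropna().astype(str))
        unseen = sorted(seen - known)
        if unseen:
            raise SchemaError(f"covariate {name!r}: unseen level(s) {unseen}")
        out = pd.DataFrame(
            {
                f"{name}[{lvl}]": (values.astype(str) == lvl).astype(float)
                for lvl in levels
            }
        )
        out[values.isna().to_numpy()] = np.nan
        return out


def encode_categoricals(
    ds: EvidenceDataset, reference_levels: Mapping[str, str] | None = None
) -> EncodingPlan:
    """Build the indicator expansion plan for every categorical covariate.

    Reference levels come from ``reference_levels`` when given, falling
    back to the covariate metadata.  A reference level absent from the data
    is a configuration error.
    """
    reference_levels = dict(reference_levels or {})
    columns: dict[str, list[str]] = {}
    references: dict[str, str] = {}
    for name, meta in ds.covariate_meta.items():
        if meta.kind != "categorical":
            continue
        values = ds.covariate_column(name, pooled_fill="nan").dropna().astype(str)
        levels = sorted(values.unique())
        ref = reference_levels.get(name, meta.reference)
        if ref is None:
            raise SchemaError(f"covariate {name!r}: no reference level declared")
        if ref not in levels:
            raise SchemaError(
                f"covariate {name!r}: reference level {ref!r} absent from data"
            )
        columns[name] = [lvl for lvl in levels if lvl != ref]
        references[name] = ref
    return EncodingPlan(columns=columns, references=references)
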