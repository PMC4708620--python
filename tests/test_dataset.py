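"""Loading, validation, currency standardization, centring, and encoding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cemeta as cm
from cemeta.dataset import CurrencyLookupError


def test_write_load_roundtrip(tiny_ds, tmp_path):
    """Writing then loading reproduces numeric fields and maps exactly."""
    paths = cm.write_dataset(tiny_ds, tmp_path)
    ds2 = cm.load_dataset(
        paths["estimates"], paths["studies"], paths["countries"], paths["meta"]
    )
    for col in ("delta_c", "delta_e", "d_x"):
        np.testing.assert_array_equal(
            tiny_ds.estimates[col].to_numpy(), ds2.estimates[col].to_numpy()
        )
    assert ds2.n_estimates == 4 and ds2.n_studies == 2 and ds2.n_countries == 2
    assert list(ds2.studies["countries"]) == [("GBR",), ("DEU",)]
    assert ds2.covariate_meta["d_cat"].reference == "No"
    assert ds2.covariate_meta["d_cat"].kind == "categorical"


@pytest.mark.parametrize(
    "mutation, needle",
    [
        (lambda est, stu, cty: est.assign(study_id=["S1", "S1", "S9", "S2"]), "S9"),
        (lambda est, stu, cty: est.assign(estimate_id=["E1", "E1", "E3", "E4"]), "E1"),
        (
            lambda est, stu, cty: est.assign(delta_c=[1.0, np.nan, 2.0, 3.0]),
            "delta_c",
        ),
        (
            lambda est, stu, cty: est.assign(country_code=["GBR", "GBR", "XXX", "DEU"]),
            "XXX",
        ),
    ],
)
def test_schema_errors_name_the_offender(tiny_ds, mutation, needle):
    est = mutation(tiny_ds.estimates, tiny_ds.studies, tiny_ds.countries)
    broken = cm.EvidenceDataset(
        est, tiny_ds.studies, tiny_ds.countries, tiny_ds.covariate_meta
    )
    with pytest.raises(cm.SchemaError, match=needle):
        broken.validate()


# ---------------------------------------------------------------------------
# currency standardization

_PPP = {"GBP": 1.0, "EUR": 1.1, "XTS": 2.0}
_DEFL = {
    ("GBP", 2010): 1.0,
    ("XTS", 2005): 1.0,
    ("XTS", 2010): 1.10,
    ("EUR", 2000): 0.9,
    ("EUR", 2010): 1.08,
}
_EURO = {"DEM": 1.95583}


@pytest.mark.parametrize(
    "amount, currency, year, expected",
    [
        (100.0, "GBP", 2010, 100.0),  # identity
        (100.0, "XTS", 2005, 55.0),  # 100 * 1.10 / 2
    ],
)
def test_standardize_cost_formula(amount, currency, year, expected):
    got = cm.standardize_cost(amount, currency, year, _PPP, _DEFL, _EURO)
    assert got == pytest.approx(expected)


def test_legacy_currency_equals_prescaled_euro():
    """Converting DEM equals converting the fixed-rate EUR amount directly."""
    via_legacy = cm.standardize_cost(195.583, "DEM", 2000, _PPP, _DEFL, _EURO)
    direct = cm.standardize_cost(100.0, "EUR", 2000, _PPP, _DEFL, _EURO)
    assert via_legacy == pytest.approx(direct)


def test_standardize_cost_missing_entry_names_key():
    with pytest.raises(CurrencyLookupError, match="XTS"):
        cm.standardize_cost(1.0, "XTS", 1999, _PPP, _DEFL, _EURO)


@given(
    a=st.floats(-1e6, 1e6, allow_nan=False),
    b=st.floats(-1e6, 1e6, allow_nan=False),
)
def test_standardize_cost_is_linear(a, b):
    f = lambda x: cm.standardize_cost(x, "XTS", 2005, _PPP, _DEFL, _EURO)
    assert f(a) + f(b) == pytest.approx(f(a + b), abs=1e-6)


# ---------------------------------------------------------------------------
# centring

def test_centering_zero_weighted_mean_and_idempotence(tiny_ds):
    c1 = cm.center_covariates(tiny_ds)
    for name in ("d_x", "s_z", "c_w"):
        col = c1.covariate_column(name).to_numpy(dtype=float)
        assert abs(col.mean()) < 1e-9
        assert c1.covariate_meta[name].centering_constant is not None
    c2 = cm.center_covariates(c1)
    np.testing.assert_allclose(
        c2.covariate_column("d_x").to_numpy(), c1.covariate_column("d_x").to_numpy()
    )
    # original constants preserved through the second (no-op) pass
    assert c2.covariate_meta["d_x"].centering_constant == pytest.approx(2.5)


def test_centering_constant_column_gives_zeros(tiny_ds):
    ds = tiny_ds.copy()
    ds.estimates["d_x"] = 6.676
    centered = cm.center_covariates(ds)
    np.testing.assert_allclose(centered.estimates["d_x"].to_numpy(), 0.0)


def test_centering_categorical_is_type_error(tiny_ds):
    ds = tiny_ds.copy()
    ds.covariate_meta["d_cat"].center = True
    with pytest.raises(TypeError, match="d_cat"):
        cm.center_covariates(ds)


@given(values=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=4))
def test_centering_preserves_pairwise_differences(tiny_ds, values):
    ds = tiny_ds.copy()
    ds.estimates["d_x"] = values
    centered = cm.center_covariates(ds)
    before = np.subtract.outer(values, values)
    after_col = centered.estimates["d_x"].to_numpy()
    after = np.subtract.outer(after_col, after_col)
    np.testing.assert_allclose(before, after, rtol=0, atol=1e-6)


# ---------------------------------------------------------------------------
# categorical encoding

def test_encode_age_bands_five_indicators(statins_ds):
    ds, _ = statins_ds
    plan = cm.encode_categoricals(ds)
    names = plan.indicator_names("d_age_band")
    assert len(names) == 5
    assert all("<45" not in n for n in names)


def test_encode_binary_and_reference_rows(tiny_ds):
    plan = cm.encode_categoricals(tiny_ds)
    assert plan.columns["d_cat"] == ["Yes"]
    block = plan.expand("d_cat", tiny_ds.estimates["d_cat"])
    np.testing.assert_array_equal(block["d_cat[Yes]"].to_numpy(), [0, 1, 0, 1])


def test_encode_missing_reference_is_error(tiny_ds):
    with pytest.raises(cm.SchemaError, match="Maybe"):
        cm.encode_categoricals(tiny_ds, {"d_cat": "Maybe"})


def test_encode_unseen_level_errors_at_expansion(tiny_ds):
    plan = cm.encode_categoricals(tiny_ds)
    with pytest.raises(cm.SchemaError, match="Unknown"):
        plan.expand("d_cat", pd.Series(["No", "Unknown"]))
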