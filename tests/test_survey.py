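"""Survey estimators: wealth index, shares, uptake, imputation rules."""

import numpy as np
import pandas as pd
import pytest

from dcea.io import ValidationError, missing_share_vector, wealth_quintile_scheme
from dcea.survey import (
    compute_wealth_index,
    estimate_opportunity_cost_shares,
    estimate_prevalence_shares,
    estimate_uptake,
    impute_missing_prevalence,
    impute_missing_uptake,
)
from dcea.synth import SurveyMicrodata, SyntheticConfig, generate_survey

from conftest import build_microdata


def test_wealth_score_boundaries():
    md = build_microdata()
    hh = md.households.copy()
    asset_cols = md.asset_columns
    hh.loc[0, asset_cols] = 1  # owns everything
    hh.loc[1, asset_cols] = 0  # owns nothing
    index = compute_wealth_index(SurveyMicrodata(hh, md.persons, md.deaths))
    assert index.scores.loc[0] == 100.0
    assert index.scores.loc[1] == 0.0
    assert index.quintiles.isin(range(1, 6)).all()


def test_quintiles_equal_person_weight():
    md = build_microdata(households_per_quintile=200)
    index = compute_wealth_index(md)
    counts = index.quintiles.value_counts()
    assert (counts == 200).all()


def test_wealth_score_monotone_in_latent_wealth():
    md = generate_survey(SyntheticConfig(n_households=5000, seed=13))
    index = compute_wealth_index(md)
    df = md.households.assign(score=index.scores.reindex(md.households["household_id"]).to_numpy())
    means = df.groupby("latent_quintile")["score"].mean()
    assert means.is_monotonic_increasing


def test_prevalence_shares_exact(scheme):
    md = build_microdata(cases_per_quintile=(36, 16, 23, 13, 12))
    index = compute_wealth_index(md)
    shares = estimate_prevalence_shares(md, "flu", index, scheme)
    assert shares.values == pytest.approx((0.36, 0.16, 0.23, 0.13, 0.12))

    md = build_microdata(cases_per_quintile=(40, 0, 0, 0, 0))
    shares = estimate_prevalence_shares(md, "flu", compute_wealth_index(md), scheme)
    assert shares.values == pytest.approx((1, 0, 0, 0, 0))

    md = build_microdata(cases_per_quintile=(10, 10, 10, 10, 10))
    shares = estimate_prevalence_shares(md, "flu", compute_wealth_index(md), scheme)
    assert shares.values == pytest.approx((0.2,) * 5)


def test_prevalence_no_cases_is_missing(scheme):
    md = build_microdata()
    shares = estimate_prevalence_shares(md, "flu", compute_wealth_index(md), scheme)
    assert shares.is_fully_missing


def test_uptake_rates(scheme):
    md = build_microdata(
        cases_per_quintile=(100, 50, 50, 50, 50),
        care_per_quintile=(48, 0, 50, 25, 10),
    )
    uptake = estimate_uptake(md, "flu", compute_wealth_index(md), scheme)
    assert uptake.values == pytest.approx((0.48, 0.0, 1.0, 0.5, 0.2))


def test_uptake_missing_where_no_cases(scheme):
    md = build_microdata(cases_per_quintile=(10, 0, 10, 10, 10),
                         care_per_quintile=(5, 0, 10, 0, 0))
    uptake = estimate_uptake(md, "flu", compute_wealth_index(md), scheme)
    arr = uptake.as_array()
    assert np.isnan(arr[1])
    assert arr[0] == pytest.approx(0.5)


def test_oc_shares_public_only(scheme):
    md = build_microdata(
        cases_per_quintile=(50, 50, 50, 50, 50),
        care_per_quintile=(23, 22, 20, 19, 16),
    )
    shares = estimate_opportunity_cost_shares(md, compute_wealth_index(md), scheme)
    assert shares.values == pytest.approx((0.23, 0.22, 0.20, 0.19, 0.16))

    # non-public episodes are excluded from numerator and denominator
    md = build_microdata(
        cases_per_quintile=(50, 50, 50, 50, 50),
        care_per_quintile=(10, 10, 10, 10, 10),
        provider="private",
    )
    with pytest.raises(ValueError, match="public"):
        estimate_opportunity_cost_shares(md, compute_wealth_index(md), scheme)


def test_worked_example_inputs_recovered(worked_example_microdata, scheme):
    md = worked_example_microdata
    index = compute_wealth_index(md)
    d = estimate_prevalence_shares(md, "flu", index, scheme)
    e = estimate_uptake(md, "flu", index, scheme)
    assert d.values == pytest.approx((0.36, 0.16, 0.23, 0.13, 0.12))
    assert e.values == pytest.approx((0.48, 0.39, 0.46, 0.49, 0.43))


def test_estimators_invariant_to_row_order(scheme):
    md = build_microdata(
        cases_per_quintile=(30, 20, 10, 5, 5), care_per_quintile=(10, 10, 5, 5, 0)
    )
    rng = np.random.default_rng(0)
    perm_h = md.households.sample(frac=1, random_state=1).reset_index(drop=True)
    perm_p = md.persons.sample(frac=1, random_state=2).reset_index(drop=True)
    shuffled = SurveyMicrodata(perm_h, perm_p, md.deaths)
    for est in (estimate_prevalence_shares, estimate_uptake):
        a = est(md, "flu", compute_wealth_index(md), scheme).as_array()
        b = est(shuffled, "flu", compute_wealth_index(shuffled), scheme).as_array()
        np.testing.assert_allclose(a, b, equal_nan=True)


def test_impute_prevalence_mean(scheme):
    v1 = missing_share_vector("prevalence_share", scheme).with_values(
        (0.4, 0.1, 0.2, 0.2, 0.1)
    )
    v2 = v1.with_values((0.2, 0.3, 0.2, 0.2, 0.1))
    missing = missing_share_vector("prevalence_share", scheme)
    completed, flags = impute_missing_prevalence({"a": v1, "b": v2, "c": missing})
    assert completed["c"].values == pytest.approx((0.3, 0.2, 0.2, 0.2, 0.1))
    assert flags == {"a": False, "b": False, "c": True}
    # single observed vector: imputation copies it
    completed, _ = impute_missing_prevalence({"a": v1, "c": missing})
    assert completed["c"].values == pytest.approx(v1.values)
    # no missing vectors: identity
    completed, flags = impute_missing_prevalence({"a": v1, "b": v2})
    assert completed == {"a": v1, "b": v2}
    with pytest.raises(ValueError):
        impute_missing_prevalence({"a": missing})


def test_impute_uptake_subgroup_means(scheme):
    from dcea.io import ShareVector

    e1 = ShareVector((0.4, 0.5, 0.5, 0.5, 0.5), "uptake_rate", scheme)
    e2 = ShareVector((0.6, 0.5, 0.5, 0.5, 0.5), "uptake_rate", scheme)
    partial = ShareVector(
        (float("nan"), 0.7, 0.5, 0.5, 0.5), "uptake_rate", scheme
    )
    completed, flags = impute_missing_uptake({"a": e1, "b": e2, "c": partial})
    # missing poorest entry filled with mean of observed poorest uptakes
    assert completed["c"].values[0] == pytest.approx(0.5)
    # observed entries kept
    assert completed["c"].values[1] == pytest.approx(0.7)
    assert flags["c"] and not flags["a"]

    whole_row = ShareVector((float("nan"),) * 5, "uptake_rate", scheme)
    completed, _ = impute_missing_uptake({"a": e1, "b": e2, "c": whole_row})
    assert completed["c"].values == pytest.approx((0.5, 0.5, 0.5, 0.5, 0.5))

    with pytest.raises(ValueError, match="no observed uptake"):
        impute_missing_uptake({"a": whole_row})
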