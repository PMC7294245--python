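"""Stage 1: allocation, benefits, opportunity cost, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcea.examples import (
    ROTAVIRUS_TOTAL_COST,
    rotavirus_example,
    rotavirus_full_coverage,
    rotavirus_inputs,
)
from dcea.impact import (
    allocate_eligible,
    direct_benefit_distribution,
    full_coverage_scenario,
    net_benefit_distribution,
    opportunity_cost_distribution,
    total_cost,
)
from dcea.io import (
    InterventionRecord,
    OpportunityCostModel,
    ShareVector,
    ValidationError,
    missing_share_vector,
    wealth_quintile_scheme,
)


def test_allocate_eligible():
    record, prevalence, _, _ = rotavirus_inputs()
    eligible = allocate_eligible(record, prevalence)
    assert eligible[0] == pytest.approx(187_668)
    assert eligible.sum() == pytest.approx(record.eligible_population)

    concentrated = prevalence.with_values((1, 0, 0, 0, 0))
    assert allocate_eligible(record, concentrated)[0] == record.eligible_population

    zero = InterventionRecord("z", 0, 1.0, 0.1)
    assert allocate_eligible(zero, prevalence).sum() == 0

    with pytest.raises(ValidationError, match="imputation"):
        allocate_eligible(record, missing_share_vector("prevalence_share", prevalence.scheme))


def test_direct_benefit_distribution():
    record, prevalence, uptake, _ = rotavirus_inputs()
    benefit = direct_benefit_distribution(record, prevalence, uptake)
    assert round(benefit[0]) == 12_611
    assert round(benefit.sum()) == 33_302

    full = direct_benefit_distribution(
        record, prevalence, uptake.with_values((1.0,) * 5)
    )
    assert round(full.sum()) == 72_982

    none = InterventionRecord("none", record.eligible_population, 0.69, 0.0)
    assert direct_benefit_distribution(none, prevalence, uptake).sum() == 0


def test_opportunity_cost_distribution():
    _, _, _, oc = rotavirus_inputs()
    dist = opportunity_cost_distribution(ROTAVIRUS_TOTAL_COST, oc)
    assert round(dist[0]) == 3_052
    assert round(dist.sum()) == 13_268
    assert opportunity_cost_distribution(0.0, oc).sum() == 0

    flat = OpportunityCostModel(
        dollars_per_daly=oc.dollars_per_daly,
        shares=oc.shares.with_values((0.2,) * 5),
    )
    np.testing.assert_allclose(
        opportunity_cost_distribution(100 * 61.0, flat), np.full(5, 20.0)
    )
    with pytest.raises(ValidationError):
        OpportunityCostModel(dollars_per_daly=0.0, shares=oc.shares)


def test_total_cost_modes():
    record, prevalence, uptake, _ = rotavirus_inputs()
    assert total_cost(record, mode="fixed", fixed_value=809_318) == 809_318
    assert total_cost(record, mode="per_eligible") == pytest.approx(359_697)
    expected = 521_300 * 0.69 * float(
        np.sum(prevalence.as_array() * uptake.as_array())
    )
    assert total_cost(record, uptake, prevalence, "per_treated") == pytest.approx(expected)
    assert total_cost(
        InterventionRecord("free", 100, 0.0, 0.1), uptake, prevalence, "per_treated"
    ) == 0
    with pytest.raises(ValidationError):
        total_cost(record, mode="fixed")
    with pytest.raises(ValidationError):
        total_cost(record, mode="bogus")


def test_net_benefit_box_values():
    result = rotavirus_example()
    assert round(result.total_net_benefit) == 20_034
    assert round(result.net_benefit[0]) == 9_560
    assert round(result.net_benefit_shares[0], 2) == 0.48


def test_per_use_net_benefit_formula():
    assert round(0.14 - 0.69 / 61, 2) == 0.13


def test_zero_net_benefit_when_oc_equals_benefit():
    record, prevalence, uptake, oc = rotavirus_inputs()
    result = net_benefit_distribution(record, prevalence, uptake, oc, "per_treated")
    # construct oc exactly offsetting the direct benefit
    benefit = np.asarray(result.direct_benefit)
    shares = benefit / benefit.sum()
    oc_match = OpportunityCostModel(
        dollars_per_daly=1.0,
        shares=oc.shares.with_values(shares),
    )
    matched = net_benefit_distribution(
        record, prevalence, uptake, oc_match, "fixed", fixed_cost=benefit.sum()
    )
    np.testing.assert_allclose(matched.net_benefit, 0.0, atol=1e-9)


def test_full_coverage_scenario():
    full = rotavirus_full_coverage()
    assert round(full.total_direct_benefit) == 72_982

    record, prevalence, uptake, oc = rotavirus_inputs()
    already_full = uptake.with_values((1.0,) * 5)
    a = full_coverage_scenario(record, prevalence, already_full, oc, "per_treated")
    b = net_benefit_distribution(record, prevalence, already_full, oc, "per_treated")
    np.testing.assert_allclose(a.net_benefit, b.net_benefit)


def test_full_coverage_can_hurt_the_richest():
    """When extra opportunity cost outpaces extra benefit in the richest
    quintile, its net benefit falls under full coverage."""
    scheme = wealth_quintile_scheme()
    record = InterventionRecord("x", 100_000, 5.0, 0.05)
    prevalence = ShareVector((0.4, 0.3, 0.2, 0.08, 0.02), "prevalence_share", scheme)
    uptake = ShareVector((0.2, 0.2, 0.2, 0.2, 0.9), "uptake_rate", scheme)
    oc = OpportunityCostModel(
        61.0, ShareVector((0.1, 0.1, 0.1, 0.1, 0.6), "opportunity_cost_share", scheme)
    )
    current = net_benefit_distribution(record, prevalence, uptake, oc, "per_treated")
    full = full_coverage_scenario(record, prevalence, uptake, oc, "per_treated")
    assert full.net_benefit[-1] < current.net_benefit[-1]
    assert full.total_direct_benefit > current.total_direct_benefit


@settings(max_examples=100, derandomize=True)
@given(
    a=st.floats(min_value=0, max_value=1e7),
    b=st.floats(min_value=-2, max_value=5),
    c=st.floats(min_value=0, max_value=500),
    k=st.floats(min_value=1, max_value=200),
    raw_d=st.lists(st.floats(min_value=0.01, max_value=1), min_size=5, max_size=5),
    raw_e=st.lists(st.floats(min_value=0, max_value=1), min_size=5, max_size=5),
    raw_f=st.lists(st.floats(min_value=0.01, max_value=1), min_size=5, max_size=5),
)
def test_conservation_against_brute_force(a, b, c, k, raw_d, raw_e, raw_f):
    """Random instances match element-by-element recomputation, and the
    subgroup totals conserve A, cost/k and benefit - cost/k."""
    scheme = wealth_quintile_scheme()
    d = np.array(raw_d) / np.sum(raw_d)
    f = np.array(raw_f) / np.sum(raw_f)
    record = InterventionRecord("r", a, c, b)
    prevalence = ShareVector(tuple(d), "prevalence_share", scheme)
    uptake = ShareVector(tuple(raw_e), "uptake_rate", scheme)
    oc = OpportunityCostModel(k, ShareVector(tuple(f), "opportunity_cost_share", scheme))
    result = net_benefit_distribution(record, prevalence, uptake, oc, "per_treated")

    cost = a * c * float(np.sum(d * np.array(raw_e)))
    for g in range(5):
        assert result.eligible[g] == pytest.approx(a * d[g], rel=1e-12)
        assert result.direct_benefit[g] == pytest.approx(
            a * b * d[g] * raw_e[g], rel=1e-12, abs=1e-12
        )
        assert result.opportunity_cost[g] == pytest.approx(
            f[g] * cost / k, rel=1e-12, abs=1e-12
        )
    assert np.sum(result.eligible) == pytest.approx(a, rel=1e-9, abs=1e-9)
    assert result.total_opportunity_cost == pytest.approx(cost / k, rel=1e-9, abs=1e-9)
    assert result.total_net_benefit == pytest.approx(
        result.total_direct_benefit - cost / k, rel=1e-9, abs=1e-9
    )


def test_monotonicity_in_uptake():
    """Holding cost fixed, raising any uptake entry raises that
    subgroup's net benefit."""
    record, prevalence, uptake, oc = rotavirus_inputs()
    base = net_benefit_distribution(
        record, prevalence, uptake, oc, "fixed", ROTAVIRUS_TOTAL_COST
    )
    bumped = uptake.with_values(
        tuple(min(1.0, v + 0.1) for v in uptake.values)
    )
    more = net_benefit_distribution(
        record, prevalence, bumped, oc, "fixed", ROTAVIRUS_TOTAL_COST
    )
    assert np.all(more.net_benefit >= base.net_benefit)
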