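"""Stage 3: Atkinson EDE, equity plane, priority orderings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcea.impact import DistributionalResult
from dcea.inequality import (
    EquityPlanePoint,
    apply_intervention,
    atkinson_ede,
    equity_impact,
    quadrant_counts,
    rank_and_select,
)
from dcea.io import ValidationError, residence_scheme, wealth_quintile_scheme
from dcea.lifetable import HALEDistribution


def _dist(values, scheme=None):
    return HALEDistribution(scheme or wealth_quintile_scheme(), tuple(values))


def _result(nhb, scheme=None, name="x"):
    scheme = scheme or wealth_quintile_scheme()
    zeros = (0.0,) * scheme.n_groups
    return DistributionalResult(
        name=name, scheme=scheme, eligible=zeros, treated=zeros,
        direct_benefit=tuple(nhb), opportunity_cost=zeros, total_cost=0.0,
    )


def test_flat_distribution_has_no_inequality():
    for eps in (0.0, 1.0, 2.0, 10.0, 25.0):
        r = atkinson_ede(_dist([50.0] * 5), eps)
        assert r.ede == pytest.approx(50.0, rel=1e-12)
        assert r.atkinson_index == pytest.approx(0.0, abs=1e-12)


def test_ede_closed_forms():
    scheme = residence_scheme(rural_share=0.5)
    dist = HALEDistribution(scheme, (40.0, 60.0))
    # eps=2 is the harmonic mean
    assert atkinson_ede(dist, 2.0).ede == pytest.approx(2 / (1 / 40 + 1 / 60), rel=1e-12)
    # eps=0 is the mean
    assert atkinson_ede(dist, 0.0).ede == pytest.approx(50.0)
    # eps=1 is the geometric mean
    assert atkinson_ede(dist, 1.0).ede == pytest.approx(np.sqrt(40 * 60), rel=1e-12)


def test_urban_rural_cost_of_inequality():
    scheme = residence_scheme()  # 85% rural
    dist = HALEDistribution(scheme, (53.18, 49.15))
    r = atkinson_ede(dist, 10.0)
    assert round(r.cost_of_inequality, 2) == 0.24


def test_continuity_at_unit_aversion():
    dist = _dist([49.85, 51.0, 55.30, 53.0, 52.0])
    geo = atkinson_ede(dist, 1.0).ede
    for eps in (1 - 1e-8, 1 + 1e-8):
        assert atkinson_ede(dist, eps).ede == pytest.approx(geo, abs=1e-9)


@settings(max_examples=300, derandomize=True)
@given(
    values=st.lists(
        st.floats(min_value=1.0, max_value=80.0), min_size=5, max_size=5
    ),
    eps=st.floats(min_value=0.1, max_value=25.0),
)
def test_ede_below_mean_unless_flat(values, eps):
    dist = _dist(values)
    r = atkinson_ede(dist, eps)
    assert r.ede <= r.mean + 1e-9
    if max(values) - min(values) > 1e-3:
        assert r.ede < r.mean
    assert -1e-12 <= r.atkinson_index < 1.0


@settings(max_examples=300, derandomize=True)
@given(
    values=st.lists(st.floats(min_value=5.0, max_value=80.0), min_size=5, max_size=5),
    eps=st.floats(min_value=0.5, max_value=15.0),
    frac=st.floats(min_value=0.0, max_value=1.0),
)
def test_transfer_principle(values, eps, frac):
    """Moving health from a better-off to a worse-off group (mean
    preserved) never decreases the EDE."""
    lo, hi = int(np.argmin(values)), int(np.argmax(values))
    if lo == hi:
        return
    gap = values[hi] - values[lo]
    amount = frac * gap / 2.0
    after = list(values)
    after[lo] += amount
    after[hi] -= amount
    before_ede = atkinson_ede(_dist(values), eps).ede
    after_ede = atkinson_ede(_dist(after), eps).ede
    assert after_ede >= before_ede - 1e-9


def test_domain_errors():
    with pytest.raises(ValidationError):
        atkinson_ede(_dist([50.0] * 5), -1.0)
    with pytest.raises(ValidationError):
        HALEDistribution(wealth_quintile_scheme(), (50.0, 50.0, 50.0, 50.0, -1.0))


def test_apply_intervention():
    scheme = wealth_quintile_scheme(100.0)  # 20 persons per quintile
    base = _dist([50.0] * 5, scheme)
    unchanged = apply_intervention(base, _result([0.0] * 5, scheme))
    assert unchanged.values == base.values

    poorest_only = apply_intervention(base, _result([17.0, 0, 0, 0, 0], scheme))
    assert poorest_only.values[0] == pytest.approx(50.0 + 17.0 / 20.0)
    assert poorest_only.values[1:] == base.values[1:]

    with pytest.raises(ValidationError, match="poorest"):
        apply_intervention(base, _result([-2000.0, 0, 0, 0, 0], scheme))


def test_uniform_gain_translation_property():
    """A uniform +c per person raises the mean by exactly c and the EDE
    by at least c (the power mean is superadditive for aversion > 0)
    and at most c plus the baseline cost of inequality."""
    scheme = wealth_quintile_scheme(100.0)
    base = _dist([45.0, 48.0, 50.0, 52.0, 55.0], scheme)
    c = 2.0
    post = apply_intervention(base, _result([c * 20.0] * 5, scheme))
    r0, r1 = atkinson_ede(base, 10.0), atkinson_ede(post, 10.0)
    assert r1.mean - r0.mean == pytest.approx(c, rel=1e-12)
    gain = r1.ede - r0.ede
    assert c - 1e-12 <= gain <= c + r0.cost_of_inequality + 1e-12


def test_equity_impact_signs():
    scheme = wealth_quintile_scheme(100.0)
    base = _dist([45.0, 48.0, 50.0, 52.0, 55.0], scheme)
    origin = equity_impact(base, base, 10.0, name="nothing")
    assert origin.delta_nhb == 0.0 and origin.delta_ede == 0.0

    worst_off = apply_intervention(base, _result([10.0, 0, 0, 0, 0], scheme))
    p = equity_impact(base, worst_off, 10.0, name="pro-poor")
    assert p.delta_nhb == pytest.approx(10.0, rel=1e-9)
    assert p.inequality_impact > 0

    best_off = apply_intervention(base, _result([0, 0, 0, 0, 10.0], scheme))
    q = equity_impact(base, best_off, 10.0, name="pro-rich")
    assert q.inequality_impact < 0


def test_quadrant_assignment_and_counts():
    pts = [
        EquityPlanePoint("a", 1.0, 2.0),    # +NHB, +equity
        EquityPlanePoint("b", 1.0, 0.5),    # +NHB, -equity
        EquityPlanePoint("c", -1.0, 0.5),   # -NHB, +equity
        EquityPlanePoint("d", -1.0, -2.0),  # -NHB, -equity
    ]
    assert [p.quadrant[:2] for p in pts] == ["Q1", "Q2", "Q3", "Q4"]
    counts = quadrant_counts(pts)
    assert sum(counts.values()) == len(pts)


def test_rank_and_select():
    with pytest.raises(ValidationError):
        rank_and_select([])

    all_negative = [
        EquityPlanePoint("a", -1.0, -2.0),
        EquityPlanePoint("b", -3.0, -1.0),
    ]
    ordering = rank_and_select(all_negative)
    assert not ordering.selected_by_nhb and not ordering.selected_by_ede

    # an intervention with negative NHB but positive EDE change appears
    # only in the EDE-based selection
    pts = [
        EquityPlanePoint("good", 5.0, 6.0),
        EquityPlanePoint("equity_only", -0.5, 0.4),
    ]
    ordering = rank_and_select(pts)
    assert "equity_only" not in ordering.selected_by_nhb
    assert "equity_only" in ordering.selected_by_ede
    assert ordering.symmetric_difference == {"equity_only"}

    ties = [EquityPlanePoint("b", 1.0, 1.0), EquityPlanePoint("a", 1.0, 1.0)]
    assert rank_and_select(ties).by_nhb == ("a", "b")
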