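"""Stage 4: declarative scenario transforms and the sensitivity suite.

Each scenario is a named list of transforms, each touching one input of
the base-case analysis:

* ``equal_prevalence`` / ``tilt_prevalence`` — flatten each
  intervention's prevalence shares, or tilt them towards the poor
  (poorest & poorer x1.1, richer & richest x0.9, middle unchanged,
  renormalised).
* ``equal_uptake`` / ``tilt_uptake`` — give every quintile the
  intervention's population-average uptake, or tilt uptake towards the
  poor (clipped to [0, 1], no renormalisation — uptake is a rate, not a
  share).
* ``oc_rate:<k>`` / ``equal_oc`` / ``tilt_oc`` — change the marginal
  productivity of expenditure ($/DALY), or flatten/tilt the
  opportunity-cost shares.
* ``baseline:<mode>`` — swap in an alternative baseline HALE
  distribution (e.g. one whose mortality pattern uses offspring deaths
  up to age 20 only).
* ``aversion:<eps>`` — change the inequality-aversion parameter.

Transforms are pure: scenario runs never mutate base-case inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .impact import net_benefit_distribution
from .inequality import (
    EquityPlanePoint,
    apply_intervention,
    atkinson_ede,
    equity_impact,
    quadrant_counts,
)
from .io import (
    AnalysisConfig,
    InterventionRecord,
    OpportunityCostModel,
    ShareVector,
    ValidationError,
)
from .lifetable import HALEDistribution

logger = logging.getLogger("dcea")

#: wealth-quintile tilt: which positions move up / down
_TILT_UP = (0, 1)  # poorest, poorer
_TILT_DOWN = (3, 4)  # richer, richest


def tilt_shares(
    shares: ShareVector,
    factor_low: float = 1.1,
    factor_high: float = 0.9,
    renormalize: bool | None = None,
) -> ShareVector:
    """Tilt a five-group wealth vector towards the disadvantaged end.

    The two poorest entries are multiplied by ``factor_low``, the two
    richest by ``factor_high``, the middle left unchanged.
    Sum-constrained kinds (prevalence, opportunity cost) are
    renormalised to 1 by default; uptake rates are clipped to [0, 1]
    without renormalisation (a warning is logged when clipping bites).
    """
    if shares.scheme.dimension_name != "wealth" or shares.scheme.n_groups != 5:
        raise ValidationError("tilt is defined for five wealth quintiles")
    arr = shares.as_array().copy()
    for i in _TILT_UP:
        arr[i] *= factor_low
    for i in _TILT_DOWN:
        arr[i] *= factor_high
    if shares.kind == "uptake_rate":
        if renormalize:
            raise ValidationError("uptake rates are not sum-constrained")
        clipped = np.clip(arr, 0.0, 1.0)
        if np.any(clipped != arr):
            logger.warning("tilted uptake clipped to [0, 1]")
        arr = clipped
    else:
        if renormalize is None or renormalize:
            arr = arr / arr.sum()
    return shares.with_values(arr)


def equalize_shares(shares: ShareVector, prevalence: ShareVector | None = None) -> ShareVector:
    """Flatten a share vector.

    Sum-constrained kinds become 1/n each.  Uptake becomes the
    intervention's population-average uptake — the prevalence-weighted
    mean sum(D_g E_g) — replicated across quintiles, so total
    utilisation is preserved.
    """
    n = shares.scheme.n_groups
    if shares.kind == "uptake_rate":
        if prevalence is None:
            raise ValidationError("equalising uptake requires the prevalence shares")
        avg = float(np.sum(prevalence.as_array() * shares.as_array()))
        return shares.with_values([avg] * n)
    return shares.with_values([1.0 / n] * n)


@dataclass(frozen=True)
class Scenario:
    """A named list of input transforms (disjoint by construction)."""

    name: str
    transforms: tuple[str, ...] = ()


#: the standard sensitivity grid: one change per scenario
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("base_case"),
    Scenario("equal_prevalence", ("equal_prevalence",)),
    Scenario("more_unequal_prevalence", ("tilt_prevalence",)),
    Scenario("equal_uptake", ("equal_uptake",)),
    Scenario("more_unequal_uptake", ("tilt_uptake",)),
    Scenario("oc_rate_37", ("oc_rate:37",)),
    Scenario("oc_rate_116", ("oc_rate:116",)),
    Scenario("equal_oc", ("equal_oc",)),
    Scenario("more_unequal_oc", ("tilt_oc",)),
    Scenario("children_only_baseline", ("baseline:children_only",)),
    Scenario("aversion_2", ("aversion:2",)),
    Scenario("aversion_25", ("aversion:25",)),
)

_KNOWN_TRANSFORMS = {
    "equal_prevalence",
    "tilt_prevalence",
    "equal_uptake",
    "tilt_uptake",
    "equal_oc",
    "tilt_oc",
    "oc_rate",
    "baseline",
    "aversion",
}


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregate package impact and per-intervention plane for one scenario."""

    scenario: str
    delta_nhb: float  # summed over package interventions, DALYs
    delta_ede: float  # population-scaled EDE change, DALYs
    quadrants: dict[str, int]
    n_nhb_improving: int
    n_ede_improving: int
    n_inequality_improving: int
    points: tuple[EquityPlanePoint, ...] = field(repr=False, default=())

    @property
    def inequality_impact(self) -> float:
        return self.delta_ede - self.delta_nhb

    def to_row(self) -> dict:
        row = {
            "name": self.scenario,
            "delta_nhb": self.delta_nhb,
            "delta_ede": self.delta_ede,
            "inequality_impact": self.inequality_impact,
        }
        row.update({f"n_{k.split()[0]}": v for k, v in self.quadrants.items()})
        row["n_nhb_improving"] = self.n_nhb_improving
        row["n_ede_improving"] = self.n_ede_improving
        row["n_inequality_improving"] = self.n_inequality_improving
        return row


def _parse(transform: str) -> tuple[str, str | None]:
    head, _, arg = transform.partition(":")
    if head not in _KNOWN_TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    return head, (arg or None)


def run_scenario(
    scenario: Scenario,
    catalog: list[InterventionRecord],
    prevalence: dict[str, ShareVector],
    uptake: dict[str, ShareVector],
    baseline: HALEDistribution,
    config: AnalysisConfig,
    alt_baselines: dict[str, HALEDistribution] | None = None,
    fixed_costs: dict[str, float] | None = None,
) -> ScenarioResult:
    """Evaluate one scenario over the whole catalog.

    Returns the aggregate package impact (summed over ``in_ehp``
    interventions) plus the per-intervention equity plane for the full
    catalog.
    """
    prev = dict(prevalence)
    upt = dict(uptake)
    oc = config.opportunity_cost
    base = baseline
    aversion = config.aversion

    for t in scenario.transforms:
        head, arg = _parse(t)
        if head == "equal_prevalence":
            prev = {k: equalize_shares(v) for k, v in prev.items()}
        elif head == "tilt_prevalence":
            prev = {k: tilt_shares(v) for k, v in prev.items()}
        elif head == "equal_uptake":
            upt = {k: equalize_shares(v, prev[k]) for k, v in upt.items()}
        elif head == "tilt_uptake":
            upt = {k: tilt_shares(v) for k, v in upt.items()}
        elif head == "equal_oc":
            oc = replace(oc, shares=equalize_shares(oc.shares))
        elif head == "tilt_oc":
            oc = replace(oc, shares=tilt_shares(oc.shares))
        elif head == "oc_rate":
            if arg is None:
                raise ValidationError("oc_rate transform needs a $/DALY value")
            oc = replace(oc, dollars_per_daly=float(arg))
        elif head == "baseline":
            if alt_baselines is None or arg not in alt_baselines:
                raise ValidationError(f"no alternative baseline named {arg!r}")
            base = alt_baselines[arg]
        elif head == "aversion":
            if arg is None:
                raise ValidationError("aversion transform needs a value")
            aversion = float(arg)

    pop = base.scheme.total_population
    points: list[EquityPlanePoint] = []
    package_nhb = np.zeros(base.scheme.n_groups)
    for record in catalog:
        result = net_benefit_distribution(
            record,
            prev[record.name],
            upt[record.name],
            oc,
            cost_mode=config.cost_mode,
            fixed_cost=(fixed_costs or {}).get(record.name),
        )
        post = apply_intervention(base, result)
        points.append(
            equity_impact(
                base, post, aversion, name=record.name, in_ehp=record.in_ehp
            )
        )
        if record.in_ehp:
            package_nhb += result.net_benefit

    # aggregate package effect: add the summed package NHB to baseline
    pops = np.asarray(base.scheme.population_counts, dtype=float)
    post_pkg = HALEDistribution(
        base.scheme, tuple(base.as_array() + package_nhb / pops)
    )
    ede_base = atkinson_ede(base, aversion)
    ede_post = atkinson_ede(post_pkg, aversion)
    delta_nhb = float(package_nhb.sum())
    delta_ede = pop * (ede_post.ede - ede_base.ede)

    return ScenarioResult(
        scenario=scenario.name,
        delta_nhb=delta_nhb,
        delta_ede=delta_ede,
        quadrants=quadrant_counts(points),
        n_nhb_improving=sum(p.delta_nhb > 0 for p in points),
        n_ede_improving=sum(p.delta_ede > 0 for p in points),
        n_inequality_improving=sum(p.inequality_impact > 0 for p in points),
        points=tuple(points),
    )


def run_scenario_suite(
    catalog: list[InterventionRecord],
    prevalence: dict[str, ShareVector],
    uptake: dict[str, ShareVector],
    baseline: HALEDistribution,
    config: AnalysisConfig,
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS,
    alt_baselines: dict[str, HALEDistribution] | None = None,
    fixed_costs: dict[str, float] | None = None,
) -> list[ScenarioResult]:
    """Run the base case plus every scenario; base case comes first."""
    all_scenarios = list(scenarios)
    if not all_scenarios or all_scenarios[0].transforms:
        all_scenarios.insert(0, Scenario("base_case"))
    return [
        run_scenario(
            s, catalog, prevalence, uptake, baseline, config,
            alt_baselines, fixed_costs,
        )
        for s in all_scenarios
    ]
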