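"""Stage 1: per-subgroup direct benefit, opportunity cost and net benefit.

An intervention with eligible population A, incremental benefit per use
B (DALYs averted) and incremental cost per use C (USD) is split across
subgroups using the survey shares:

* eligible_g  = A x D_g                     (prevalence shares D)
* treated_g   = A x D_g x E_g               (uptake rates E)
* benefit_g   = A x B x D_g x E_g           (equal efficacy per use)
* oc_g        = F_g x total_cost / k        (opportunity-cost shares F,
                                             marginal productivity k $/DALY)
* nhb_g       = benefit_g - oc_g

Three total-cost conventions are supported: ``per_treated`` (the
default: cost is incurred only for delivered uses, A x C x sum(D x E)),
``per_eligible`` (A x C) and ``fixed`` (a supplied programme cost used
verbatim).  Published programme budgets do not always equal A x C, so
``fixed`` lets a known budget be pinned exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    InterventionRecord,
    OpportunityCostModel,
    ShareVector,
    SubgroupScheme,
    ValidationError,
)

COST_MODES = ("per_eligible", "per_treated", "fixed")


@dataclass(frozen=True)
class DistributionalResult:
    """Per-subgroup decomposition of one intervention's net health benefit."""

    name: str
    scheme: SubgroupScheme
    eligible: tuple[float, ...]  # A x D
    treated: tuple[float, ...]  # A x D x E
    direct_benefit: tuple[float, ...]  # DALYs averted
    opportunity_cost: tuple[float, ...]  # DALYs forgone
    total_cost: float  # USD

    @property
    def net_benefit(self) -> np.ndarray:
        return np.asarray(self.direct_benefit) - np.asarray(self.opportunity_cost)

    @property
    def total_direct_benefit(self) -> float:
        return float(np.sum(self.direct_benefit))

    @property
    def total_opportunity_cost(self) -> float:
        return float(np.sum(self.opportunity_cost))

    @property
    def total_net_benefit(self) -> float:
        return self.total_direct_benefit - self.total_opportunity_cost

    @property
    def net_benefit_shares(self) -> np.ndarray | None:
        """Subgroup shares of net benefit; None unless the total is positive."""
        total = self.total_net_benefit
        if total <= 0:
            return None
        return self.net_benefit / total

    def to_row(self) -> dict:
        row = {"name": self.name}
        for prefix, values in (
            ("eligible", self.eligible),
            ("treated", self.treated),
            ("benefit", self.direct_benefit),
            ("oc", self.opportunity_cost),
            ("nhb", self.net_benefit),
        ):
            for label, v in zip(self.scheme.labels, values):
                row[f"{prefix}_{label}"] = float(v)
            row[f"{prefix}_total"] = float(np.sum(values))
        row["total_cost_usd"] = self.total_cost
        return row


def _require_complete(shares: ShareVector, what: str) -> np.ndarray:
    arr = shares.as_array()
    if np.any(np.isnan(arr)):
        raise ValidationError(
            f"{what} has missing entries; run imputation before Stage 1"
        )
    return arr


def allocate_eligible(
    record: InterventionRecord, prevalence: ShareVector
) -> np.ndarray:
    """Eligible persons per subgroup: A x D.  Sums to A."""
    d = _require_complete(prevalence, "prevalence")
    return record.eligible_population * d


def direct_benefit_distribution(
    record: InterventionRecord,
    prevalence: ShareVector,
    uptake: ShareVector,
) -> np.ndarray:
    """DALYs averted per subgroup at current uptake: A x B x D x E.

    The benefit per use B is the same for every subgroup (equal-efficacy
    assumption).
    """
    d = _require_complete(prevalence, "prevalence")
    e = _require_complete(uptake, "uptake")
    if np.any((e < 0) | (e > 1)):
        raise ValidationError("uptake rates must be in [0, 1]")
    return record.eligible_population * record.incremental_benefit * d * e


def total_cost(
    record: InterventionRecord,
    uptake: ShareVector | None = None,
    prevalence: ShareVector | None = None,
    mode: str = "per_treated",
    fixed_value: float | None = None,
) -> float:
    """Total incremental cost of the programme under the chosen convention."""
    if mode not in COST_MODES:
        raise ValidationError(f"unknown cost mode {mode!r}")
    if mode == "fixed":
        if fixed_value is None:
            raise ValidationError("fixed cost mode requires a supplied value")
        return float(fixed_value)
    base = record.eligible_population * record.incremental_cost
    if mode == "per_eligible":
        return float(base)
    d = _require_complete(prevalence, "prevalence")
    e = _require_complete(uptake, "uptake")
    return float(base * np.sum(d * e))


def opportunity_cost_distribution(
    total_incremental_cost: float, oc: OpportunityCostModel
) -> np.ndarray:
    """DALYs forgone per subgroup: F x (total cost / k)."""
    if total_incremental_cost < 0:
        raise ValidationError("total cost must be >= 0")
    f = _require_complete(oc.shares, "opportunity-cost shares")
    return f * (total_incremental_cost / oc.dollars_per_daly)


def net_benefit_distribution(
    record: InterventionRecord,
    prevalence: ShareVector,
    uptake: ShareVector,
    oc: OpportunityCostModel,
    cost_mode: str = "per_treated",
    fixed_cost: float | None = None,
) -> DistributionalResult:
    """Full Stage-1 decomposition for one intervention."""
    if prevalence.scheme != uptake.scheme or prevalence.scheme != oc.shares.scheme:
        raise ValidationError("prevalence, uptake and oc shares must share a scheme")
    eligible = allocate_eligible(record, prevalence)
    e = _require_complete(uptake, "uptake")
    treated = eligible * e
    benefit = direct_benefit_distribution(record, prevalence, uptake)
    cost = total_cost(record, uptake, prevalence, cost_mode, fixed_cost)
    oc_dist = opportunity_cost_distribution(cost, oc)
    return DistributionalResult(
        name=record.name,
        scheme=prevalence.scheme,
        eligible=tuple(eligible),
        treated=tuple(treated),
        direct_benefit=tuple(benefit),
        opportunity_cost=tuple(oc_dist),
        total_cost=cost,
    )


def full_coverage_scenario(
    record: InterventionRecord,
    prevalence: ShareVector,
    uptake: ShareVector,
    oc: OpportunityCostModel,
    cost_mode: str = "per_treated",
    fixed_cost: float | None = None,
) -> DistributionalResult:
    """Stage-1 decomposition at 100% uptake (E_g = 1 everywhere).

    The total cost is rescaled to full coverage under the configured
    convention: per-treated and per-eligible both become A x C; a fixed
    budget is scaled in proportion to treated persons.
    """
    full_uptake = uptake.with_values([1.0] * uptake.scheme.n_groups)
    if cost_mode == "fixed":
        if fixed_cost is None:
            raise ValidationError("fixed cost mode requires a supplied value")
        d = _require_complete(prevalence, "prevalence")
        e = _require_complete(uptake, "uptake")
        coverage = float(np.sum(d * e))
        scaled = fixed_cost * (np.sum(d) / coverage) if coverage > 0 else fixed_cost
        return net_benefit_distribution(
            record, prevalence, full_uptake, oc, "fixed", scaled
        )
    return net_benefit_distribution(record, prevalence, full_uptake, oc, cost_mode)
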