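"""Stage 3: Atkinson inequality valuation and the health equity impact plane.

The equally distributed equivalent (EDE) of a health distribution is the
uniform level of health society values as much as the actual unequal
distribution.  With inequality aversion epsilon and subgroup health
``h_g`` carrying population-share weights ``w_g``:

    h_EDE = [ sum_g w_g h_g^(1 - eps) ]^(1 / (1 - eps))        (eps != 1)
    h_EDE = exp( sum_g w_g ln h_g )                            (eps = 1)

eps = 0 returns the population mean; larger eps weights the worse-off
more heavily.  The Atkinson index is 1 - EDE/mean, and mean - EDE is the
per-person cost of inequality in healthy life years.

An intervention's equity impact compares its population net health
benefit (dNHB, the change in total health) with its EDE impact (dEDE,
the change in EDE scaled to population).  dEDE - dNHB is the value of
its effect on inequality: positive for interventions that favour the
worse-off, negative for ones that widen the health gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .impact import DistributionalResult
from .io import ValidationError
from .lifetable import HALEDistribution

QUADRANTS = {
    (True, True): "Q1 (+NHB, +equity)",
    (True, False): "Q2 (+NHB, -equity)",
    (False, True): "Q3 (-NHB, +equity)",
    (False, False): "Q4 (-NHB, -equity)",
}


@dataclass(frozen=True)
class EDEResult:
    """Mean, EDE and Atkinson summary of a health distribution."""

    mean: float
    ede: float
    aversion: float

    @property
    def atkinson_index(self) -> float:
        return 1.0 - self.ede / self.mean

    @property
    def cost_of_inequality(self) -> float:
        """Mean minus EDE: per-person health society would forgo to
        eliminate the inequality."""
        return self.mean - self.ede


def atkinson_ede(
    distribution: HALEDistribution, aversion: float
) -> EDEResult:
    """Atkinson EDE of a grouped health distribution.

    Subgroups are treated as homogeneous blocks with population-share
    weights.  Health must be strictly positive (the power mean is
    undefined otherwise for aversion >= 1).
    """
    if aversion < 0:
        raise ValidationError("aversion must be >= 0")
    h = distribution.as_array()
    w = distribution.weights
    if np.any(h <= 0):
        raise ValidationError("health values must be positive for the Atkinson EDE")
    mean = float(np.sum(w * h))
    if aversion == 0:
        ede = mean
    elif aversion == 1:
        ede = float(np.exp(np.sum(w * np.log(h))))
    else:
        # stable weighted power mean: log-sum-exp with expm1/log1p so the
        # eps -> 1 limit agrees with the geometric mean to ~1e-14
        p = 1.0 - aversion
        z = p * np.log(h)
        m = float(np.max(z))
        t = float(np.sum(w * np.expm1(z - m)))
        ede = float(np.exp((m + np.log1p(t)) / p))
    return EDEResult(mean=mean, ede=ede, aversion=aversion)


def apply_intervention(
    baseline: HALEDistribution, result: DistributionalResult
) -> HALEDistribution:
    """Add an intervention's per-person net benefit to baseline HALE.

    nhb_g DALYs averted spread over population_g persons add
    nhb_g / population_g healthy years per person; losses are allowed
    as long as health stays positive.
    """
    if result.scheme.labels != baseline.scheme.labels:
        raise ValidationError("intervention and baseline use different schemes")
    pops = np.asarray(baseline.scheme.population_counts, dtype=float)
    h = baseline.as_array() + result.net_benefit / pops
    for label, v in zip(baseline.scheme.labels, h):
        if v <= 0:
            raise ValidationError(
                f"post-intervention health non-positive in subgroup {label!r}"
            )
    return HALEDistribution(baseline.scheme, tuple(h))


@dataclass(frozen=True)
class EquityPlanePoint:
    """One intervention's position on the health equity impact plane."""

    name: str
    delta_nhb: float  # population net health benefit, DALYs
    delta_ede: float  # change in EDE x population, DALYs
    in_ehp: bool = False

    @property
    def inequality_impact(self) -> float:
        """Value of the inequality effect in DALYs: dEDE - dNHB."""
        return self.delta_ede - self.delta_nhb

    @property
    def quadrant(self) -> str:
        return QUADRANTS[(self.delta_nhb > 0, self.inequality_impact > 0)]

    def to_row(self) -> dict:
        return {
            "name": self.name,
            "delta_nhb": self.delta_nhb,
            "delta_ede": self.delta_ede,
            "inequality_impact": self.inequality_impact,
            "quadrant": self.quadrant,
            "in_ehp": int(self.in_ehp),
        }


def equity_impact(
    baseline: HALEDistribution,
    post: HALEDistribution,
    aversion: float,
    name: str = "",
    in_ehp: bool = False,
    total_population: float | None = None,
) -> EquityPlanePoint:
    """Equity-plane placement of a baseline -> post health change."""
    if baseline.scheme.labels != post.scheme.labels:
        raise ValidationError("baseline and post use different schemes")
    pop = (
        total_population
        if total_population is not None
        else baseline.scheme.total_population
    )
    base = atkinson_ede(baseline, aversion)
    after = atkinson_ede(post, aversion)
    return EquityPlanePoint(
        name=name,
        delta_nhb=pop * (after.mean - base.mean),
        delta_ede=pop * (after.ede - base.ede),
        in_ehp=in_ehp,
    )


def quadrant_counts(points: list[EquityPlanePoint]) -> dict[str, int]:
    counts = {q: 0 for q in QUADRANTS.values()}
    for p in points:
        counts[p.quadrant] += 1
    return counts


@dataclass(frozen=True)
class PriorityOrdering:
    """Rankings and selections under the two decision rules."""

    by_nhb: tuple[str, ...]  # descending population net health benefit
    by_ede: tuple[str, ...]  # descending EDE impact
    selected_by_nhb: frozenset[str]  # dNHB > 0
    selected_by_ede: frozenset[str]  # dEDE > 0

    @property
    def symmetric_difference(self) -> frozenset[str]:
        return self.selected_by_nhb ^ self.selected_by_ede


def rank_and_select(points: list[EquityPlanePoint]) -> PriorityOrdering:
    """Compare prioritisation by net health benefit vs by EDE change.

    Ties are broken by intervention name for determinism.
    """
    if not points:
        raise ValidationError("need at least one equity-plane point")
    by_nhb = sorted(points, key=lambda p: (-p.delta_nhb, p.name))
    by_ede = sorted(points, key=lambda p: (-p.delta_ede, p.name))
    return PriorityOrdering(
        by_nhb=tuple(p.name for p in by_nhb),
        by_ede=tuple(p.name for p in by_ede),
        selected_by_nhb=frozenset(p.name for p in points if p.delta_nhb > 0),
        selected_by_ede=frozenset(p.name for p in points if p.delta_ede > 0),
    )


def plot_equity_plane(points: list[EquityPlanePoint], path) -> None:
    """Scatter the interventions on the equity impact plane (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    xs = [p.inequality_impact for p in points]
    ys = [p.delta_nhb for p in points]
    colors = ["tab:blue" if p.in_ehp else "tab:gray" for p in points]
    ax.scatter(xs, ys, c=colors, alpha=0.7)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("Inequality impact (ΔEDE − ΔNHB, DALYs)")
    ax.set_ylabel("Population net health benefit (DALYs)")
    ax.set_title("Health equity impact plane")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
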