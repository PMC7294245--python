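"""Stage 2: abridged lifetables and Sullivan health-adjusted life expectancy.

Subgroup mortality is modelled as a reference age-specific rate schedule
(e.g. national burden-of-disease estimates) scaled by per-subgroup
relative factors estimated from survey death reports (siblings at all
ages, offspring up to age 35).  Factors are normalised so the
population-weighted mean rate per band equals the reference rate.

The abridged lifetable uses mid-interval deaths (nax = n/2) in every
band, so nqx = n nMx / (1 + (n/2) nMx) and nLx = n (lx + l(x+n)) / 2.
The table is closed at 75: by default it truncates there (survey death
reports above 75 are discarded), or, when a terminal rate is supplied,
the open interval contributes l(75) / M person-years.

The Sullivan method discounts person-years by the proportion of time
lived in ill health: HALE = sum_b nLx_b (1 - yld_b) / l0, with yld_b a
dimensionless years-lost-to-disability proportion per band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ShareVector, SubgroupScheme, ValidationError
from .synth import MORTALITY_BANDS, SurveyMicrodata

logger = logging.getLogger("dcea")


@dataclass(frozen=True)
class AgeBandScheme:
    """Contiguous age bands starting at 0."""

    edges: tuple[float, ...]  # band b spans [edges[b], edges[b+1])

    def __post_init__(self) -> None:
        if self.edges[0] != 0:
            raise ValidationError("age bands must start at 0")
        if any(nxt <= prev for prev, nxt in zip(self.edges[:-1], self.edges[1:])):
            raise ValidationError("age band edges must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        e = np.asarray(self.edges, dtype=float)
        return np.diff(e)

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))


def default_age_bands() -> AgeBandScheme:
    """5-year bands to 55 plus one 55-75 band; the table closes at 75."""
    return AgeBandScheme(tuple(float(a) for a in range(0, 60, 5)) + (75.0,))


# Synthetic default schedules for running the pipeline end-to-end without
# external inputs: an illustrative high-mortality reference nMx schedule
# and YLD proportions per band, representative in shape (high infant
# mortality, low child mortality, rising adult mortality) but not taken
# from any published source.
SYNTHETIC_REFERENCE_RATES: tuple[float, ...] = (
    0.018, 0.003, 0.002, 0.003, 0.005, 0.006, 0.008, 0.010, 0.012, 0.014, 0.016, 0.040,
)
SYNTHETIC_YLD_PROPORTIONS: tuple[float, ...] = (
    0.06, 0.04, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12, 0.14,
)


@dataclass(frozen=True)
class MortalityPattern:
    """Per-subgroup, per-band relative mortality factors.

    ``factors[g, b]`` scales the reference rate in band ``b`` for
    subgroup ``g``; the population-weighted mean factor is 1 per band.
    """

    scheme: SubgroupScheme
    age_bands: AgeBandScheme
    factors: np.ndarray  # (n_groups, n_bands)
    source_mode: str = "siblings_and_children"

    def __post_init__(self) -> None:
        if self.factors.shape != (self.scheme.n_groups, self.age_bands.n_bands):
            raise ValidationError("factor matrix shape mismatch")
        if np.any(self.factors <= 0):
            raise ValidationError("mortality factors must be positive")


def derive_mortality_pattern(
    microdata: SurveyMicrodata,
    quintiles: pd.Series,
    scheme: SubgroupScheme,
    mode: str = "siblings_and_children",
    age_bands: AgeBandScheme | None = None,
) -> MortalityPattern:
    """Relative mortality factors from reported sibling/offspring deaths.

    The respondent's subgroup proxies that of their siblings and
    children.  ``children_only`` mode keeps offspring deaths up to age
    20 only.  Death rates per band are deaths per respondent; factors
    are rates normalised so their respondent-weighted mean is 1.  A
    subgroup-band with zero deaths everywhere keeps factor 1 (logged).
    """
    if mode not in ("siblings_and_children", "children_only"):
        raise ValidationError(f"unknown mortality source mode {mode!r}")
    bands = age_bands or default_age_bands()
    deaths = microdata.deaths
    if mode == "children_only":
        deaths = deaths[(deaths["relation"] == "child") & (deaths["age_at_death"] <= 20)]
    else:
        deaths = deaths[deaths["age_at_death"] < bands.edges[-1]]

    hh_q = quintiles
    respondents = hh_q.value_counts().reindex(range(1, scheme.n_groups + 1), fill_value=0)
    weights = respondents.to_numpy() / respondents.sum()

    factors = np.ones((scheme.n_groups, bands.n_bands))
    death_q = deaths["household_id"].map(hh_q)
    band_idx = np.searchsorted(bands.edges[1:], deaths["age_at_death"].to_numpy(), side="right")
    for b in range(bands.n_bands):
        in_band = band_idx == b
        counts = (
            death_q[in_band]
            .value_counts()
            .reindex(range(1, scheme.n_groups + 1), fill_value=0)
            .to_numpy()
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(respondents.to_numpy() > 0, counts / respondents.to_numpy(), 0.0)
        mean_rate = float(np.sum(weights * rates))
        if mean_rate <= 0:
            logger.warning("no deaths in band %s; factors set to 1", bands.bands[b])
            continue
        f = rates / mean_rate
        if np.any(f <= 0):
            logger.warning(
                "zero exposure/deaths for some subgroup in band %s; imputing factor 1",
                bands.bands[b],
            )
            f = np.where(f > 0, f, 1.0)
            f = f / np.sum(weights * f)  # re-normalise after imputation
        factors[:, b] = f
    return MortalityPattern(scheme, bands, factors, mode)


@dataclass(frozen=True)
class Lifetable:
    """Abridged lifetable columns for one subgroup."""

    age_bands: AgeBandScheme
    nMx: np.ndarray
    nqx: np.ndarray
    lx: np.ndarray  # length n_bands + 1, l[0] = 1
    nLx: np.ndarray
    ex: np.ndarray

    @property
    def life_expectancy(self) -> float:
        return float(self.ex[0])


def build_lifetable(
    reference_rates: np.ndarray,
    factor: np.ndarray | float = 1.0,
    age_bands: AgeBandScheme | None = None,
    terminal_rate: float | None = None,
) -> Lifetable:
    """Abridged lifetable from per-band mortality rates.

    ``reference_rates`` are nMx per band; ``factor`` scales them (scalar
    or per band).  With no ``terminal_rate`` the table truncates at the
    last band edge; otherwise the open terminal interval contributes
    l(end)/terminal_rate person-years.
    """
    bands = age_bands or default_age_bands()
    rates = np.asarray(reference_rates, dtype=float) * np.asarray(factor, dtype=float)
    if rates.shape != (bands.n_bands,):
        raise ValidationError("reference rates must have one entry per band")
    if np.any(rates <= 0):
        raise ValidationError("mortality rates must be positive")
    n = bands.widths
    nqx = n * rates / (1.0 + (n / 2.0) * rates)
    nqx = np.clip(nqx, 0.0, 1.0)
    lx = np.empty(bands.n_bands + 1)
    lx[0] = 1.0
    for b in range(bands.n_bands):
        lx[b + 1] = lx[b] * (1.0 - nqx[b])
    nLx = n * (lx[:-1] + lx[1:]) / 2.0
    terminal_Lx = 0.0
    if terminal_rate is not None:
        if terminal_rate <= 0:
            raise ValidationError("terminal rate must be positive")
        terminal_Lx = lx[-1] / terminal_rate
    # remaining person-years above each exact age
    tail = np.concatenate([np.cumsum((nLx)[::-1])[::-1], [0.0]]) + terminal_Lx
    with np.errstate(divide="ignore", invalid="ignore"):
        ex_all = np.where(lx > 0, tail / lx, 0.0)
    return Lifetable(bands, rates, nqx, lx, nLx, ex_all[:-1])


def subgroup_lifetables(
    reference_rates: np.ndarray,
    pattern: MortalityPattern,
    terminal_rate: float | None = None,
) -> dict[str, Lifetable]:
    """One lifetable per subgroup: reference rates x subgroup factors."""
    return {
        label: build_lifetable(
            reference_rates,
            pattern.factors[g],
            pattern.age_bands,
            terminal_rate,
        )
        for g, label in enumerate(pattern.scheme.labels)
    }


def distribute_yld(
    total_yld_by_band: np.ndarray,
    disease_shares: ShareVector,
) -> np.ndarray:
    """Split population YLD proportions into per-subgroup YLD proportions.

    The subgroup's rate is the population rate scaled by its share of
    the disease burden over its population share, so the
    population-weighted mean rate is preserved per band.  Returns an
    array of shape (n_groups, n_bands).
    """
    shares = disease_shares.as_array()
    pop_shares = disease_shares.scheme.population_shares
    total = np.asarray(total_yld_by_band, dtype=float)
    ratio = shares / pop_shares
    return ratio[:, None] * total[None, :]


def sullivan_hale(lifetable: Lifetable, yld_rates: np.ndarray) -> float:
    """Health-adjusted life expectancy at birth via the Sullivan method."""
    yld = np.asarray(yld_rates, dtype=float)
    if yld.shape != (lifetable.age_bands.n_bands,):
        raise ValidationError("need one YLD proportion per band")
    if np.any(yld < 0) or np.any(yld >= 1):
        raise ValidationError("YLD proportions must be in [0, 1)")
    return float(np.sum(lifetable.nLx * (1.0 - yld)) / lifetable.lx[0])


@dataclass(frozen=True)
class HALEDistribution:
    """Per-subgroup health-adjusted life expectancy with population weights."""

    scheme: SubgroupScheme
    values: tuple[float, ...]  # healthy life years per subgroup

    def __post_init__(self) -> None:
        if len(self.values) != self.scheme.n_groups:
            raise ValidationError("one HALE value per subgroup required")
        if any(v <= 0 for v in self.values):
            raise ValidationError("HALE values must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.scheme.population_shares

    @property
    def mean(self) -> float:
        return float(np.sum(self.weights * self.as_array()))

    def to_row(self) -> dict:
        row = {"name": self.scheme.dimension_name}
        row.update({label: v for label, v in zip(self.scheme.labels, self.values)})
        row["mean"] = self.mean
        return row


def baseline_hale_distribution(
    reference_rates: np.ndarray,
    pattern: MortalityPattern,
    total_yld_by_band: np.ndarray,
    disease_shares: ShareVector,
    terminal_rate: float | None = None,
) -> HALEDistribution:
    """Baseline HALE per subgroup from rates, factors and YLD burden."""
    tables = subgroup_lifetables(reference_rates, pattern, terminal_rate)
    yld = distribute_yld(total_yld_by_band, disease_shares)
    values = []
    for g, label in enumerate(pattern.scheme.labels):
        yld_g = np.clip(yld[g], 0.0, 0.999)
        values.append(sullivan_hale(tables[label], yld_g))
    return HALEDistribution(pattern.scheme, tuple(values))
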