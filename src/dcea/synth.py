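"""Synthetic household-survey and intervention-catalog generator.

Emulates the structure of the national surveys the analysis draws on
(integrated household surveys with two-week illness recall and
care-seeking questions, demographic surveys with sibling/offspring death
reports, and an asset module) so that every pipeline stage is testable
without external microdata.

Mechanism
---------
Each household carries a latent wealth score ``u ~ Uniform(0, 1)``.
Asset ownership is independent Bernoulli given ``u`` with a logistic
link, ``P(own asset j) = expit(beta * (u - tau_j))``, thresholds
``tau_j`` spread over (0, 1).  A household's latent quintile (from
``u``) drives multiplicative gradients on disease prevalence,
care-seeking and mortality hazards.  Disease assignment is categorical
(at most one two-week illness code per person), which preserves each
disease's marginal probability exactly — the generator's expected
prevalence shares, uptake rates and opportunity-cost shares are
therefore available in closed form (:meth:`SyntheticConfig.expected_*`)
for parameter-recovery checks.

All randomness flows from the single configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    InterventionRecord,
    ShareVector,
    SubgroupScheme,
    wealth_quintile_scheme,
)

logger = logging.getLogger("dcea")

#: provider codes counted as the public sector (the benefits-package
#: providers: government and church-based facilities)
PUBLIC_PROVIDERS = frozenset({"government", "church"})

#: age bands used for simulated death reports: 5-year bands to 55,
#: one 55-75 band; deaths above 75 are not generated
MORTALITY_BANDS: tuple[tuple[int, int], ...] = tuple(
    (a, a + 5) for a in range(0, 55, 5)
) + ((55, 75),)

#: offspring deaths are only reported up to age 35
OFFSPRING_MAX_AGE = 35


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DiseaseConfig:
    """Prevalence and care-seeking parameters for one illness code.

    Quintile gradients are multiplicative factors (most disadvantaged
    first) applied to the base rate, clipped to [0, 1].
    """

    name: str
    base_prevalence: float
    prevalence_gradient: tuple[float, float, float, float, float]
    base_uptake: float
    uptake_gradient: tuple[float, float, float, float, float]

    def prevalence_by_quintile(self) -> np.ndarray:
        p = self.base_prevalence * np.asarray(self.prevalence_gradient)
        return np.clip(p, 0.0, 1.0)

    def uptake_by_quintile(self) -> np.ndarray:
        u = self.base_uptake * np.asarray(self.uptake_gradient)
        return np.clip(u, 0.0, 1.0)


def _default_diseases() -> tuple[DiseaseConfig, ...]:
    # Calibrated so that, with equal-size quintiles, the dominant
    # condition reproduces a 36/16/23/13/12 prevalence-share pattern with
    # 48/39/46/49/43 uptake, and aggregate public-sector care episodes
    # fall roughly 23/22/20/19/16 across quintiles.
    return (
        DiseaseConfig(
            "diarrhoea",
            base_prevalence=0.16,
            prevalence_gradient=(1.80, 0.80, 1.15, 0.65, 0.60),
            base_uptake=0.45,
            uptake_gradient=(48 / 45, 39 / 45, 46 / 45, 49 / 45, 43 / 45),
        ),
        DiseaseConfig(
            "fever",
            base_prevalence=0.20,
            prevalence_gradient=(0.85, 1.35, 0.95, 1.10, 1.00),
            base_uptake=0.50,
            uptake_gradient=(1.00, 1.00, 0.95, 0.95, 1.00),
        ),
        DiseaseConfig(
            "respiratory",
            base_prevalence=0.10,
            prevalence_gradient=(1.10, 1.20, 1.00, 0.95, 0.80),
            base_uptake=0.40,
            uptake_gradient=(0.95, 1.00, 1.00, 1.05, 1.10),
        ),
    )


def _default_assets() -> tuple[float, ...]:
    # 40 asset thresholds spread over the latent-wealth range: a fine,
    # near-continuous asset index in the spirit of the International
    # Wealth Index, which combines many weighted asset and housing
    # indicators into an almost continuous 0-100 score.
    return tuple(np.linspace(0.03, 0.97, 40))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic survey.

    Defaults describe a poor, predominantly rural population: 15% urban
    residence, steep socioeconomic gradients in two-week illness
    prevalence, mild gradients in care-seeking, and a 2:1
    poorest-to-richest mortality hazard ratio.
    """

    n_households: int = 1000
    urban_fraction: float = 0.15
    asset_thresholds: tuple[float, ...] = field(default_factory=_default_assets)
    asset_steepness: float = 100.0
    household_size_mean: float = 4.4
    diseases: tuple[DiseaseConfig, ...] = field(default_factory=_default_diseases)
    provider_mix: tuple[tuple[str, float], ...] = (
        ("government", 0.60),
        ("church", 0.15),
        ("private", 0.15),
        ("traditional", 0.10),
    )
    #: expected reported sibling deaths per respondent per band
    sibling_hazard: tuple[float, ...] = (
        0.030, 0.008, 0.006, 0.008, 0.010, 0.012, 0.014, 0.016, 0.018, 0.020,
        0.022, 0.060,
    )
    #: expected reported offspring deaths per respondent per band (ages < 35)
    offspring_hazard: tuple[float, ...] = (0.040, 0.010, 0.006, 0.006, 0.008, 0.008, 0.010)
    mortality_quintile_factors: tuple[float, float, float, float, float] = (
        2.0, 1.5, 1.2, 1.1, 1.0,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ValueError("n_households must be positive")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must be in [0, 1]")
        probs = [p for _, p in self.provider_mix]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("provider_mix must be a probability distribution")
        for d in self.diseases:
            if any(g <= 0 for g in d.prevalence_gradient + d.uptake_gradient):
                raise ValueError(f"{d.name}: gradient factors must be > 0")
        if any(h < 0 for h in self.sibling_hazard + self.offspring_hazard):
            raise ValueError("hazards must be >= 0")

    # -- closed-form expectations (for parameter-recovery tests) --------

    def expected_prevalence_shares(self, disease: str) -> np.ndarray:
        """Expected share of a disease's cases per latent quintile."""
        d = self._disease(disease)
        p = d.prevalence_by_quintile()
        return p / p.sum()  # equal-size quintiles

    def expected_uptake(self, disease: str) -> np.ndarray:
        return self._disease(disease).uptake_by_quintile()

    def expected_oc_shares(self) -> np.ndarray:
        """Expected public/church care-episode shares per quintile."""
        rate = np.zeros(5)
        for d in self.diseases:
            rate += d.prevalence_by_quintile() * d.uptake_by_quintile()
        return rate / rate.sum()

    def _disease(self, name: str) -> DiseaseConfig:
        for d in self.diseases:
            if d.name == name:
                return d
        raise KeyError(name)


@dataclass
class SurveyMicrodata:
    """Survey-like microdata: households, persons, reported deaths.

    ``households``: household_id, residence, latent_wealth,
    latent_quintile, asset_* indicator columns.
    ``persons``: household_id, person_id, age, disease ('' if none),
    care_sought, provider ('' unless care sought).
    ``deaths``: household_id, relation ('sibling'|'child'), age_at_death.
    """

    households: pd.DataFrame
    persons: pd.DataFrame
    deaths: pd.DataFrame

    @property
    def asset_columns(self) -> list[str]:
        return [c for c in self.households.columns if c.startswith("asset_")]

    def person_table(self) -> pd.DataFrame:
        """One row per person, household attributes joined in."""
        return self.persons.merge(self.households, on="household_id", how="left")

    def write_csv(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in (
            ("households.csv", self.households),
            ("persons.csv", self.persons),
            ("deaths.csv", self.deaths),
        ):
            p = outdir / name
            df.to_csv(p, index=False)
            paths.append(p)
        return paths

    @classmethod
    def read_csv(cls, outdir: str | Path) -> "SurveyMicrodata":
        outdir = Path(outdir)
        return cls(
            households=pd.read_csv(outdir / "households.csv"),
            persons=pd.read_csv(
                outdir / "persons.csv", keep_default_na=False,
                dtype={"disease": str, "provider": str},
            ),
            deaths=pd.read_csv(outdir / "deaths.csv"),
        )


def generate_households(config: SyntheticConfig) -> SurveyMicrodata:
    """Draw households with residence, latent wealth and asset ownership."""
    rng = np.random.default_rng(config.seed)
    n = config.n_households
    u = rng.uniform(0.0, 1.0, size=n)
    urban = rng.uniform(size=n) < config.urban_fraction
    taus = np.asarray(config.asset_thresholds)
    p_own = _expit(config.asset_steepness * (u[:, None] - taus[None, :]))
    assets = (rng.uniform(size=p_own.shape) < p_own).astype(int)
    households = pd.DataFrame(
        {
            "household_id": np.arange(n),
            "residence": np.where(urban, "urban", "rural"),
            "latent_wealth": u,
            "latent_quintile": np.minimum((u * 5).astype(int) + 1, 5),
        }
    )
    for j in range(assets.shape[1]):
        households[f"asset_{j:02d}"] = assets[:, j]

    sizes = 1 + rng.poisson(config.household_size_mean - 1.0, size=n)
    hh_ids = np.repeat(households["household_id"].to_numpy(), sizes)
    m = hh_ids.size
    persons = pd.DataFrame(
        {
            "household_id": hh_ids,
            "person_id": np.arange(m),
            "age": rng.integers(0, 80, size=m),
            "disease": np.full(m, "", dtype=object),
            "care_sought": np.zeros(m, dtype=bool),
            "provider": np.full(m, "", dtype=object),
        }
    )
    deaths = pd.DataFrame(
        {"household_id": pd.Series(dtype=int),
         "relation": pd.Series(dtype=str),
         "age_at_death": pd.Series(dtype=float)}
    )
    return SurveyMicrodata(households, persons, deaths)


def generate_disease_and_careseeking(
    microdata: SurveyMicrodata, config: SyntheticConfig
) -> SurveyMicrodata:
    """Draw two-week illness codes, care-seeking and provider codes.

    Illness is categorical per person (at most one code), with
    quintile-specific probability ``base x gradient`` per disease;
    probabilities exceeding 1 in aggregate are renormalised with a
    logged warning.  Care-seeking is Bernoulli conditional on illness;
    the provider is drawn from the configured mix.
    """
    rng = np.random.default_rng(config.seed + 1)
    persons = microdata.persons.copy()
    q = persons["household_id"].map(
        microdata.households.set_index("household_id")["latent_quintile"]
    ).to_numpy()

    diseases = config.diseases
    prev = np.stack([d.prevalence_by_quintile() for d in diseases])  # (d, 5)
    upt = np.stack([d.uptake_by_quintile() for d in diseases])
    p_person = prev[:, q - 1].T  # (n, d)
    total = p_person.sum(axis=1)
    if np.any(total > 1.0):
        logger.warning(
            "disease probabilities sum above 1 for %d persons; renormalising",
            int((total > 1.0).sum()),
        )
        p_person = np.where(total[:, None] > 1.0, p_person / total[:, None], p_person)
    # categorical draw: none vs disease codes
    cum = np.cumsum(p_person, axis=1)
    r = rng.uniform(size=len(persons))
    idx = (r[:, None] < cum).argmax(axis=1)
    has_disease = r < cum[:, -1]
    disease = np.where(has_disease, np.array([d.name for d in diseases])[idx], "")
    persons["disease"] = disease

    care_p = np.where(has_disease, upt[idx, q - 1], 0.0)
    care = rng.uniform(size=len(persons)) < care_p
    persons["care_sought"] = care

    codes = [c for c, _ in config.provider_mix]
    probs = np.array([p for _, p in config.provider_mix])
    prov_idx = rng.choice(len(codes), size=len(persons), p=probs)
    persons["provider"] = np.where(care, np.array(codes, dtype=object)[prov_idx], "")
    return SurveyMicrodata(microdata.households, persons, microdata.deaths)


def generate_mortality_reports(
    microdata: SurveyMicrodata, config: SyntheticConfig
) -> SurveyMicrodata:
    """Simulate sibling and offspring death reports per respondent.

    One respondent per household.  Reported deaths per age band are
    Poisson with mean ``hazard x quintile factor``; offspring deaths are
    only generated up to age 35.  Ages at death are uniform in the band.
    """
    rng = np.random.default_rng(config.seed + 2)
    hh = microdata.households
    q = hh["latent_quintile"].to_numpy()
    factors = np.asarray(config.mortality_quintile_factors)[q - 1]

    rows: dict[str, list] = {"household_id": [], "relation": [], "age_at_death": []}
    for relation, hazards in (
        ("sibling", config.sibling_hazard),
        ("child", config.offspring_hazard),
    ):
        for (lo, hi), hz in zip(MORTALITY_BANDS, hazards):
            if relation == "child" and lo >= OFFSPRING_MAX_AGE:
                continue
            hi_eff = min(hi, OFFSPRING_MAX_AGE) if relation == "child" else hi
            counts = rng.poisson(hz * factors)
            total = int(counts.sum())
            if total == 0:
                continue
            ids = np.repeat(hh["household_id"].to_numpy(), counts)
            ages = rng.uniform(lo, hi_eff, size=total)
            rows["household_id"].extend(ids.tolist())
            rows["relation"].extend([relation] * total)
            rows["age_at_death"].extend(ages.tolist())
    deaths = pd.DataFrame(rows)
    if len(deaths):
        deaths = deaths.sort_values(
            ["household_id", "relation", "age_at_death"]
        ).reset_index(drop=True)
    return SurveyMicrodata(microdata.households, microdata.persons, deaths)


def generate_survey(config: SyntheticConfig) -> SurveyMicrodata:
    """Full synthetic survey: households, illness, care-seeking, deaths."""
    md = generate_households(config)
    md = generate_disease_and_careseeking(md, config)
    return generate_mortality_reports(md, config)


def generate_intervention_catalog(
    m: int,
    seed: int,
    scheme: SubgroupScheme | None = None,
    in_ehp_fraction: float = 51 / 73,
    base_prevalence_shares: tuple[float, ...] = (0.36, 0.16, 0.23, 0.13, 0.12),
    base_uptake: tuple[float, ...] = (0.48, 0.39, 0.46, 0.49, 0.43),
    concentration: float = 60.0,
    missing_prevalence_fraction: float = 0.0,
    missing_uptake_fraction: float = 0.0,
) -> tuple[list[InterventionRecord], dict[str, ShareVector], dict[str, ShareVector]]:
    """Generate a catalog of ``m`` interventions with matching share tables.

    Eligible populations, unit costs and unit benefits are log-uniform
    over plausible ranges (costs $0.10-$500 per use, benefits
    0.001-5 DALYs averted per use).  Prevalence shares are Dirichlet
    draws centred on ``base_prevalence_shares``; uptake rates are
    jittered around ``base_uptake``.  A configurable fraction of rows is
    blanked out to exercise downstream imputation.  Exactly
    ``round(m * in_ehp_fraction)`` records carry the package flag.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    scheme = scheme or wealth_quintile_scheme()
    rng = np.random.default_rng(seed)
    records = []
    n_ehp = int(round(m * in_ehp_fraction))
    flags = np.zeros(m, dtype=bool)
    flags[:n_ehp] = True
    rng.shuffle(flags)
    prevalence: dict[str, ShareVector] = {}
    uptake: dict[str, ShareVector] = {}
    base_d = np.asarray(base_prevalence_shares)
    base_e = np.asarray(base_uptake)
    for i in range(m):
        name = f"intervention_{i + 1:03d}"
        a = float(np.exp(rng.uniform(np.log(1e4), np.log(2e6))))
        c = float(np.exp(rng.uniform(np.log(0.1), np.log(500.0))))
        b = float(np.exp(rng.uniform(np.log(0.001), np.log(5.0))))
        records.append(
            InterventionRecord(
                name=name,
                eligible_population=round(a),
                incremental_cost=round(c, 4),
                incremental_benefit=round(b, 5),
                in_ehp=bool(flags[i]),
            )
        )
        if rng.uniform() < missing_prevalence_fraction:
            d = (float("nan"),) * scheme.n_groups
        else:
            d = tuple(rng.dirichlet(concentration * base_d))
        if rng.uniform() < missing_uptake_fraction:
            e = (float("nan"),) * scheme.n_groups
        else:
            e = tuple(np.clip(base_e * rng.lognormal(0.0, 0.15, size=5), 0.02, 0.98))
        prevalence[name] = ShareVector(d, "prevalence_share", scheme)
        uptake[name] = ShareVector(e, "uptake_rate", scheme)
    return records, prevalence, uptake
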