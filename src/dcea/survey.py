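"""Survey estimators for the distributional inputs.

From person-level microdata this module estimates everything Stage 1
needs: an asset-based wealth index with person-weighted quintiles, each
intervention's prevalence shares (D) and uptake rates (E), the
population-wide opportunity-cost shares (F), and the mean-based
imputation rules for interventions absent from the survey.

The wealth score is ``100 x (assets owned) / (assets listed)`` — equal
asset weights, 0 when a household owns none of the listed assets and
100 when it owns all of them.  Quintile boundaries fall at the
person-weighted 20/40/60/80th percentiles of the score, with ties at a
boundary broken by household identifier so the assignment is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ShareVector, SubgroupScheme, missing_share_vector
from .synth import PUBLIC_PROVIDERS, SurveyMicrodata

logger = logging.getLogger("dcea")


@dataclass(frozen=True)
class WealthIndex:
    """Per-household asset score in [0, 100] and quintile (1=poorest)."""

    scores: pd.Series  # index: household_id
    quintiles: pd.Series  # index: household_id, values 1..5

    def quintile_of(self, household_ids) -> np.ndarray:
        return self.quintiles.reindex(household_ids).to_numpy()


def compute_wealth_index(microdata: SurveyMicrodata) -> WealthIndex:
    """Equal-weight asset score and person-weighted wealth quintiles.

    Households with no asset data are excluded (count logged).  Each
    quintile holds as close to one fifth of the survey *persons* as the
    discrete household sizes allow.
    """
    hh = microdata.households
    asset_cols = microdata.asset_columns
    if not asset_cols:
        raise ValueError("microdata has no asset columns")
    valid = hh.dropna(subset=asset_cols)
    dropped = len(hh) - len(valid)
    if dropped:
        logger.warning("excluding %d households with no asset data", dropped)
    score = 100.0 * valid[asset_cols].sum(axis=1) / len(asset_cols)
    scores = pd.Series(score.to_numpy(), index=valid["household_id"].to_numpy())

    persons_per_hh = (
        microdata.persons.groupby("household_id").size().reindex(scores.index).fillna(0)
    )
    order = np.lexsort((scores.index.to_numpy(), scores.to_numpy()))
    sorted_ids = scores.index.to_numpy()[order]
    weights = persons_per_hh.to_numpy()[order]
    cum = np.cumsum(weights)
    total = cum[-1] if len(cum) else 0
    # quintile = number of 20%-boundaries strictly below the household's
    # cumulative person weight
    frac = np.where(total > 0, cum / total, 0.0)
    q = np.minimum(np.searchsorted([0.2, 0.4, 0.6, 0.8], frac, side="left") + 1, 5)
    quintiles = pd.Series(q, index=sorted_ids).sort_index()
    return WealthIndex(scores=scores.sort_index(), quintiles=quintiles)


def _person_quintiles(
    microdata: SurveyMicrodata, index: WealthIndex
) -> pd.DataFrame:
    persons = microdata.persons.copy()
    persons["quintile"] = index.quintile_of(persons["household_id"])
    return persons.dropna(subset=["quintile"])


def estimate_prevalence_shares(
    microdata: SurveyMicrodata,
    disease_code: str,
    index: WealthIndex,
    scheme: SubgroupScheme,
) -> ShareVector:
    """Share of a disease's survey-reported cases per wealth quintile."""
    persons = _person_quintiles(microdata, index)
    cases = persons[persons["disease"] == disease_code]
    if len(cases) == 0:
        logger.warning("no reported cases of %s; marking missing", disease_code)
        return missing_share_vector("prevalence_share", scheme)
    counts = (
        cases.groupby("quintile").size().reindex(range(1, scheme.n_groups + 1), fill_value=0)
    )
    shares = counts.to_numpy() / counts.sum()
    return ShareVector(tuple(shares), "prevalence_share", scheme)


def estimate_uptake(
    microdata: SurveyMicrodata,
    disease_code: str,
    index: WealthIndex,
    scheme: SubgroupScheme,
) -> ShareVector:
    """Care-seeking rate among reported cases, per quintile.

    Quintiles with no cases get a missing (NaN) entry for imputation.
    """
    persons = _person_quintiles(microdata, index)
    cases = persons[persons["disease"] == disease_code]
    groups = range(1, scheme.n_groups + 1)
    n_cases = cases.groupby("quintile").size().reindex(groups, fill_value=0)
    n_care = (
        cases[cases["care_sought"]].groupby("quintile").size().reindex(groups, fill_value=0)
    )
    values = tuple(
        float(n_care[g]) / float(n_cases[g]) if n_cases[g] > 0 else float("nan")
        for g in groups
    )
    return ShareVector(values, "uptake_rate", scheme)


def estimate_opportunity_cost_shares(
    microdata: SurveyMicrodata,
    index: WealthIndex,
    scheme: SubgroupScheme,
) -> ShareVector:
    """Distribution of public/church care episodes across quintiles.

    Care episodes at non-public providers are excluded from both
    numerator and denominator.
    """
    persons = _person_quintiles(microdata, index)
    public = persons[persons["provider"].isin(PUBLIC_PROVIDERS)]
    if len(public) == 0:
        raise ValueError(
            "no public/church care episodes: cannot estimate opportunity-cost shares"
        )
    counts = (
        public.groupby("quintile").size().reindex(range(1, scheme.n_groups + 1), fill_value=0)
    )
    shares = counts.to_numpy() / counts.sum()
    return ShareVector(tuple(shares), "opportunity_cost_share", scheme)


# ---------------------------------------------------------------------------
# Imputation for interventions missing from the survey


def impute_missing_prevalence(
    vectors: dict[str, ShareVector],
) -> tuple[dict[str, ShareVector], dict[str, bool]]:
    """Replace fully-missing prevalence vectors by the mean distribution.

    The replacement is the element-wise mean of observed vectors,
    renormalised to sum to one.  Returns the completed vectors and a
    per-intervention imputation flag.
    """
    observed = [v for v in vectors.values() if not v.is_fully_missing]
    if not observed:
        raise ValueError("all prevalence vectors are missing; nothing to impute from")
    mean = np.mean([v.as_array() for v in observed], axis=0)
    mean = mean / mean.sum()
    out, flags = {}, {}
    for name, v in vectors.items():
        if v.is_fully_missing:
            out[name] = v.with_values(mean)
            flags[name] = True
        else:
            out[name] = v
            flags[name] = False
    return out, flags


def impute_missing_uptake(
    vectors: dict[str, ShareVector],
) -> tuple[dict[str, ShareVector], dict[str, bool]]:
    """Fill missing uptake entries with the subgroup mean across interventions.

    Only missing entries are replaced; observed entries are kept.  A
    subgroup with no observed uptake in any intervention is an error.
    """
    if not vectors:
        raise ValueError("no uptake vectors supplied")
    stacked = np.array([v.as_array() for v in vectors.values()])
    observed_any = ~np.all(np.isnan(stacked), axis=0)
    col_mean = np.full(stacked.shape[1], np.nan)
    col_mean[observed_any] = np.nanmean(stacked[:, observed_any], axis=0)
    if np.any(np.isnan(col_mean)):
        bad = np.flatnonzero(np.isnan(col_mean))
        raise ValueError(f"no observed uptake anywhere for subgroup index {bad.tolist()}")
    out, flags = {}, {}
    for name, v in vectors.items():
        arr = v.as_array()
        miss = np.isnan(arr)
        if miss.any():
            filled = np.where(miss, col_mean, arr)
            out[name] = v.with_values(filled)
            flags[name] = True
        else:
            out[name] = v
            flags[name] = False
    return out, flags
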