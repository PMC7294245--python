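"""Shared fixtures: a clean five-quintile scheme and hand-built microdata."""

import numpy as np
import pandas as pd
import pytest

from dcea.io import wealth_quintile_scheme
from dcea.synth import SurveyMicrodata

N_ASSETS = 40


@pytest.fixture
def scheme():
    return wealth_quintile_scheme()


def build_microdata(
    cases_per_quintile=(0, 0, 0, 0, 0),
    care_per_quintile=(0, 0, 0, 0, 0),
    households_per_quintile=100,
    provider="government",
    deaths=None,
):
    """Microdata with unambiguous quintiles and prescribed case counts.

    Each quintile block owns a distinct number of assets, so the
    equal-weight score separates the blocks exactly; one person per
    household.  The first ``cases_per_quintile[g]`` persons of block g
    report a disease ("flu"), of whom the first ``care_per_quintile[g]``
    sought care at ``provider``.
    """
    n = 5 * households_per_quintile
    assets_owned = np.repeat([2, 10, 18, 26, 34], households_per_quintile)
    households = pd.DataFrame(
        {
            "household_id": np.arange(n),
            "residence": "rural",
            "latent_wealth": np.repeat(np.linspace(0.1, 0.9, 5), households_per_quintile),
            "latent_quintile": np.repeat([1, 2, 3, 4, 5], households_per_quintile),
        }
    )
    for j in range(N_ASSETS):
        households[f"asset_{j:02d}"] = (j < assets_owned).astype(int)

    disease = np.full(n, "", dtype=object)
    care = np.zeros(n, dtype=bool)
    prov = np.full(n, "", dtype=object)
    for g in range(5):
        start = g * households_per_quintile
        k = cases_per_quintile[g]
        disease[start : start + k] = "flu"
        c = care_per_quintile[g]
        care[start : start + c] = True
        prov[start : start + c] = provider
    persons = pd.DataFrame(
        {
            "household_id": np.arange(n),
            "person_id": np.arange(n),
            "age": 30,
            "disease": disease,
            "care_sought": care,
            "provider": prov,
        }
    )
    if deaths is None:
        deaths = pd.DataFrame(
            {"household_id": pd.Series(dtype=int),
             "relation": pd.Series(dtype=str),
             "age_at_death": pd.Series(dtype=float)}
        )
    return SurveyMicrodata(households, persons, deaths)


@pytest.fixture
def worked_example_microdata():
    """Microdata whose estimates equal the worked example's survey inputs.

    Case counts 3600/1600/2300/1300/1200 give prevalence shares
    (0.36, 0.16, 0.23, 0.13, 0.12); care counts are chosen so uptake is
    exactly (0.48, 0.39, 0.46, 0.49, 0.43).
    """
    cases = (3600, 1600, 2300, 1300, 1200)
    care = (1728, 624, 1058, 637, 516)
    return build_microdata(
        cases_per_quintile=cases,
        care_per_quintile=care,
        households_per_quintile=3600,
    )
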