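"""Domain types, tabular readers/writers and configuration.

The analysis operates on a small set of typed containers shared by every
stage of the pipeline:

* :class:`SubgroupScheme` — an ordered stratification of the population
  (wealth quintiles or urban/rural residence), ordered from most to least
  disadvantaged.
* :class:`InterventionRecord` — one intervention's aggregate
  cost-effectiveness inputs: eligible population per year (A), incremental
  cost per use in USD (C) and incremental health benefit per use in DALYs
  averted (B).
* :class:`ShareVector` — a per-subgroup vector of prevalence shares (D),
  uptake rates (E) or opportunity-cost shares (F).  Missing entries are
  NaN, never 0: downstream imputation needs the distinction.

All tables are plain CSV (UTF-8, ``.`` decimal).  Share tables store
proportions in [0, 1]; columns whose header ends in ``%`` (or tables read
with ``percent=True``) are divided by 100 at read time, since source
documents mix the two notations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dcea")

SHARE_KINDS = ("prevalence_share", "uptake_rate", "opportunity_cost_share")
#: kinds whose non-missing vectors must sum to one
_SUM_CONSTRAINED = ("prevalence_share", "opportunity_cost_share")

WEALTH_LABELS = ("poorest", "poorer", "middle", "richer", "richest")
RESIDENCE_LABELS = ("rural", "urban")


class SchemaError(ValueError):
    """A table's columns do not match the expected schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


@dataclass(frozen=True)
class SubgroupScheme:
    """An ordered population stratification.

    Labels run from most to least disadvantaged ("poorest" → "richest";
    "rural", "urban").  ``population_counts`` are persons per subgroup.
    """

    dimension_name: str
    labels: tuple[str, ...]
    population_counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("subgroup labels must be unique")
        if len(self.population_counts) != len(self.labels):
            raise ValidationError("population_counts length must match labels")
        if any(c <= 0 for c in self.population_counts):
            raise ValidationError("population_counts must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def total_population(self) -> float:
        return float(sum(self.population_counts))

    @property
    def population_shares(self) -> np.ndarray:
        counts = np.asarray(self.population_counts, dtype=float)
        return counts / counts.sum()


def wealth_quintile_scheme(total_population: float = 17.5e6) -> SubgroupScheme:
    """Five equal-size wealth quintiles (asset-index based)."""
    per = total_population / 5.0
    return SubgroupScheme("wealth", WEALTH_LABELS, (per,) * 5)


def residence_scheme(
    total_population: float = 17.5e6, rural_share: float = 0.85
) -> SubgroupScheme:
    """Rural/urban stratification; Malawi's census split is 85/15."""
    return SubgroupScheme(
        "residence",
        RESIDENCE_LABELS,
        (total_population * rural_share, total_population * (1.0 - rural_share)),
    )


@dataclass(frozen=True)
class InterventionRecord:
    """One intervention's aggregate cost-effectiveness inputs."""

    name: str
    eligible_population: float  # persons per year (A)
    incremental_cost: float  # USD per use (C)
    incremental_benefit: float  # DALYs averted per use (B); may be negative
    in_ehp: bool = False

    def __post_init__(self) -> None:
        if self.eligible_population < 0:
            raise ValidationError(f"{self.name}: eligible_population must be >= 0")
        if self.incremental_cost < 0:
            raise ValidationError(f"{self.name}: incremental_cost must be >= 0")


@dataclass(frozen=True)
class ShareVector:
    """A per-subgroup nonnegative vector tied to a :class:`SubgroupScheme`.

    ``values`` may contain NaN for missing entries.  Fully observed
    prevalence and opportunity-cost vectors must sum to 1; uptake rates
    must each lie in [0, 1].
    """

    values: tuple[float, ...]
    kind: str
    scheme: SubgroupScheme

    def __post_init__(self) -> None:
        if self.kind not in SHARE_KINDS:
            raise ValidationError(f"unknown share kind {self.kind!r}")
        if len(self.values) != self.scheme.n_groups:
            raise ValidationError(
                f"length {len(self.values)} does not match scheme "
                f"({self.scheme.n_groups} groups)"
            )
        arr = self.as_array()
        obs = arr[~np.isnan(arr)]
        if np.any(obs < 0):
            raise ValidationError(f"{self.kind} values must be nonnegative")
        if self.kind == "uptake_rate" and np.any(obs > 1):
            raise ValidationError("uptake_rate values must be in [0, 1]")
        if self.kind in _SUM_CONSTRAINED and not np.any(np.isnan(arr)):
            if abs(obs.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"{self.kind} must sum to 1, got {obs.sum():.9f}"
                )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def is_fully_missing(self) -> bool:
        return bool(np.all(np.isnan(self.as_array())))

    @property
    def has_missing(self) -> bool:
        return bool(np.any(np.isnan(self.as_array())))

    def with_values(self, values: Iterable[float]) -> "ShareVector":
        return replace(self, values=tuple(float(v) for v in values))


def missing_share_vector(kind: str, scheme: SubgroupScheme) -> ShareVector:
    return ShareVector((float("nan"),) * scheme.n_groups, kind, scheme)


@dataclass(frozen=True)
class OpportunityCostModel:
    """Marginal productivity of health expenditure and its incidence.

    ``dollars_per_daly`` (k) is the expenditure that displaces one DALY
    elsewhere in the system (base $61).  ``shares`` (F) say which
    subgroups bear the forgone health, proxied by the distribution of
    public/church healthcare utilisation.
    """

    dollars_per_daly: float
    shares: ShareVector

    def __post_init__(self) -> None:
        if self.dollars_per_daly <= 0:
            raise ValidationError("dollars_per_daly must be positive")
        if self.shares.kind != "opportunity_cost_share":
            raise ValidationError("shares must be of kind opportunity_cost_share")


@dataclass(frozen=True)
class AnalysisConfig:
    """Top-level analysis settings."""

    aversion: float  # inequality aversion epsilon (base 10)
    opportunity_cost: OpportunityCostModel
    scheme: SubgroupScheme
    scenarios: tuple[str, ...] = ()
    seed: int = 0
    cost_mode: str = "per_treated"

    def __post_init__(self) -> None:
        if self.aversion < 0:
            raise ValidationError("aversion must be >= 0")


# ---------------------------------------------------------------------------
# Readers / writers

_CATALOG_COLUMNS = [
    "name",
    "eligible_population",
    "incremental_cost",
    "incremental_benefit",
    "in_ehp",
]

_TRUTHY = {"1", "true", "True", "TRUE", 1, True, 1.0}
_FALSY = {"0", "false", "False", "FALSE", 0, False, 0.0}


def _parse_flag(value, row: int) -> bool:
    if value in _TRUTHY:
        return True
    if value in _FALSY:
        return False
    raise ValidationError(f"row {row}: cannot parse in_ehp value {value!r}")


def read_intervention_table(path: str | Path) -> list[InterventionRecord]:
    """Read an intervention catalog CSV into records.

    Required columns: name, eligible_population, incremental_cost,
    incremental_benefit, in_ehp (0/1/true/false).
    """
    df = pd.read_csv(path, dtype={"name": str})
    for col in _CATALOG_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                InterventionRecord(
                    name=str(row.name),
                    eligible_population=float(row.eligible_population),
                    incremental_cost=float(row.incremental_cost),
                    incremental_benefit=float(row.incremental_benefit),
                    in_ehp=_parse_flag(row.in_ehp, i),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"row {i}: non-numeric cell ({exc})") from exc
    return records


def write_intervention_table(
    records: Sequence[InterventionRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "name": [r.name for r in records],
            "eligible_population": [r.eligible_population for r in records],
            "incremental_cost": [r.incremental_cost for r in records],
            "incremental_benefit": [r.incremental_benefit for r in records],
            "in_ehp": [int(r.in_ehp) for r in records],
        },
        columns=_CATALOG_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_share_table(
    path: str | Path,
    scheme: SubgroupScheme,
    kind: str,
    percent: bool = False,
) -> dict[str, ShareVector]:
    """Read a share table: one row per intervention, one column per subgroup.

    Blank cells are preserved as missing (NaN) for downstream imputation.
    A header suffix ``%`` on every subgroup column, or ``percent=True``,
    converts percentages to proportions.
    """
    df = pd.read_csv(path, dtype={"name": str})
    if "name" not in df.columns:
        raise SchemaError(f"missing 'name' column in {path}")
    cols = [c for c in df.columns if c != "name" and c != "imputed"]
    stripped = [c.rstrip("%").strip() for c in cols]
    if tuple(stripped) != tuple(scheme.labels):
        raise SchemaError(
            f"subgroup columns {stripped} do not match scheme labels "
            f"{list(scheme.labels)}"
        )
    scale = 0.01 if (percent or all(c.endswith("%") for c in cols)) else 1.0
    out: dict[str, ShareVector] = {}
    for _, row in df.iterrows():
        values = tuple(
            float(row[c]) * scale if pd.notna(row[c]) else float("nan")
            for c in cols
        )
        out[str(row["name"])] = ShareVector(values, kind, scheme)
    return out


def write_share_table(
    shares: Mapping[str, ShareVector],
    path: str | Path,
    imputed: Mapping[str, bool] | None = None,
) -> None:
    rows = []
    scheme = None
    for name, sv in shares.items():
        scheme = sv.scheme
        row = {"name": name, **dict(zip(sv.scheme.labels, sv.values))}
        if imputed is not None:
            row["imputed"] = int(imputed.get(name, False))
        rows.append(row)
    cols = ["name", *(scheme.labels if scheme else ())]
    if imputed is not None:
        cols.append("imputed")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of results (anything with ``to_row``) to CSV.

    Round-trips numeric values exactly to the formatted precision
    (9 significant digits, stable across platforms).
    """
    rows = [r.to_row() for r in results]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["name"])
    df.to_csv(path, index=False, float_format="%.9g")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scheme_raw = raw.get("scheme", {})
    if scheme_raw.get("dimension_name", "wealth") == "wealth":
        scheme = wealth_quintile_scheme(float(scheme_raw.get("total_population", 17.5e6)))
    else:
        scheme = residence_scheme(
            float(scheme_raw.get("total_population", 17.5e6)),
            float(scheme_raw.get("rural_share", 0.85)),
        )
    oc_raw = raw.get("opportunity_cost", {})
    if "dollars_per_daly" not in oc_raw:
        raise ValidationError("config is missing opportunity_cost.dollars_per_daly")
    shares = oc_raw.get("shares")
    if shares is None:
        values = tuple(1.0 / scheme.n_groups for _ in scheme.labels)
    else:
        values = tuple(float(v) for v in shares)
    oc = OpportunityCostModel(
        dollars_per_daly=float(oc_raw["dollars_per_daly"]),
        shares=ShareVector(values, "opportunity_cost_share", scheme),
    )
    return AnalysisConfig(
        aversion=float(raw.get("aversion", 10.0)),
        opportunity_cost=oc,
        scheme=scheme,
        scenarios=tuple(raw.get("scenarios", ())),
        seed=int(raw.get("seed", 0)),
        cost_mode=str(raw.get("cost_mode", "per_treated")),
    )
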