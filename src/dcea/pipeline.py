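"""End-to-end pipeline: synthesise → estimate → Stages 1–4, with a manifest.

Every stage reads and writes plain CSV in a shared working directory, so
the pipeline can be driven file-by-file from the command line or in one
call via :func:`run_pipeline`.  A JSON manifest records the
configuration hash, seed, per-stage timings and a SHA-256 digest of
every output, making reruns verifiable: the same configuration and seed
must reproduce identical digests.

Interventions are linked to survey illness codes round-robin; a
configurable fraction is left unmatched to exercise the mean-based
imputation rules.  Numeric CSV cells are written with 9 significant
digits so digests are stable across platforms.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import survey as survey_mod
from .impact import net_benefit_distribution
from .inequality import equity_impact, apply_intervention, plot_equity_plane, rank_and_select
from .io import (
    AnalysisConfig,
    OpportunityCostModel,
    ShareVector,
    read_intervention_table,
    read_share_table,
    wealth_quintile_scheme,
    write_intervention_table,
    write_results_table,
    write_share_table,
)
from .lifetable import (
    SYNTHETIC_REFERENCE_RATES,
    SYNTHETIC_YLD_PROPORTIONS,
    baseline_hale_distribution,
    derive_mortality_pattern,
)
from .sensitivity import DEFAULT_SCENARIOS, run_scenario_suite
from .synth import SurveyMicrodata, SyntheticConfig, generate_intervention_catalog, generate_survey


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-data pipeline run."""

    n_households: int = 4000
    n_interventions: int = 73
    seed: int = 7
    dollars_per_daly: float = 61.0
    aversion: float = 10.0
    cost_mode: str = "per_treated"
    unmatched_every: int = 10  # every k-th intervention lacks survey data
    run_scenarios: bool = True
    make_plot: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pooled_case_shares(microdata: SurveyMicrodata, quintiles, scheme) -> ShareVector:
    """Share of all reported illness episodes per quintile (YLD proxy)."""
    persons = microdata.persons
    q = persons["household_id"].map(quintiles)
    cases = q[persons["disease"] != ""]
    counts = cases.value_counts().reindex(range(1, scheme.n_groups + 1), fill_value=0)
    return ShareVector(
        tuple(counts.to_numpy() / counts.sum()), "prevalence_share", scheme
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Run synthesise → estimate → Stage 1 → 2 → 3 → 4 into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = wealth_quintile_scheme()
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        seed=config.seed,
    )

    def _time(stage):
        return _StageTimer(stage, manifest)

    # --- synthesise -----------------------------------------------------
    with _time("synth"):
        syn = SyntheticConfig(n_households=config.n_households, seed=config.seed)
        microdata = generate_survey(syn)
        catalog, _, _ = generate_intervention_catalog(
            config.n_interventions, seed=config.seed + 1, scheme=scheme
        )
        paths = microdata.write_csv(outdir)
        write_intervention_table(catalog, outdir / "catalog.csv")
        paths.append(outdir / "catalog.csv")

    # --- estimate (survey statistics + imputation) ----------------------
    with _time("estimate"):
        index = survey_mod.compute_wealth_index(microdata)
        disease_codes = [d.name for d in syn.diseases]
        link, prevalence, uptake = {}, {}, {}
        for i, record in enumerate(catalog):
            if config.unmatched_every and (i + 1) % config.unmatched_every == 0:
                link[record.name] = ""  # no survey counterpart → imputed
                prevalence[record.name] = ShareVector(
                    (float("nan"),) * scheme.n_groups, "prevalence_share", scheme
                )
                uptake[record.name] = ShareVector(
                    (float("nan"),) * scheme.n_groups, "uptake_rate", scheme
                )
                continue
            code = disease_codes[i % len(disease_codes)]
            link[record.name] = code
            prevalence[record.name] = survey_mod.estimate_prevalence_shares(
                microdata, code, index, scheme
            )
            uptake[record.name] = survey_mod.estimate_uptake(
                microdata, code, index, scheme
            )
        prevalence, d_flags = survey_mod.impute_missing_prevalence(prevalence)
        uptake, e_flags = survey_mod.impute_missing_uptake(uptake)
        oc_shares = survey_mod.estimate_opportunity_cost_shares(
            microdata, index, scheme
        )
        write_share_table(prevalence, outdir / "prevalence.csv", d_flags)
        write_share_table(uptake, outdir / "uptake.csv", e_flags)
        write_share_table({"all": oc_shares}, outdir / "oc_shares.csv")
        index.quintiles.rename("quintile").rename_axis("household_id").to_csv(
            outdir / "household_quintiles.csv"
        )
        paths += [
            outdir / "prevalence.csv",
            outdir / "uptake.csv",
            outdir / "oc_shares.csv",
            outdir / "household_quintiles.csv",
        ]

    oc = OpportunityCostModel(config.dollars_per_daly, oc_shares)
    analysis = AnalysisConfig(
        aversion=config.aversion,
        opportunity_cost=oc,
        scheme=scheme,
        seed=config.seed,
        cost_mode=config.cost_mode,
    )

    # --- Stage 1: distributional impact ---------------------------------
    with _time("impact"):
        results = [
            net_benefit_distribution(
                r, prevalence[r.name], uptake[r.name], oc, config.cost_mode
            )
            for r in catalog
        ]
        write_results_table(results, outdir / "impact.csv")
        paths.append(outdir / "impact.csv")

    # --- Stage 2: baseline HALE ------------------------------------------
    with _time("baseline"):
        rates = np.asarray(SYNTHETIC_REFERENCE_RATES)
        ylds = np.asarray(SYNTHETIC_YLD_PROPORTIONS)
        case_shares = _pooled_case_shares(microdata, index.quintiles, scheme)
        baselines = {}
        for mode in ("siblings_and_children", "children_only"):
            pattern = derive_mortality_pattern(
                microdata, index.quintiles, scheme, mode=mode
            )
            baselines[mode] = baseline_hale_distribution(
                rates, pattern, ylds, case_shares
            )
        baseline = baselines["siblings_and_children"]
        pd.DataFrame(
            [
                {"mode": mode, **dict(zip(scheme.labels, b.values)), "mean": b.mean}
                for mode, b in baselines.items()
            ]
        ).to_csv(outdir / "baseline_hale.csv", index=False, float_format="%.9g")
        paths.append(outdir / "baseline_hale.csv")

    # --- Stage 3: equity plane -------------------------------------------
    with _time("equity"):
        points = [
            equity_impact(
                baseline,
                apply_intervention(baseline, res),
                config.aversion,
                name=res.name,
                in_ehp=rec.in_ehp,
            )
            for rec, res in zip(catalog, results)
        ]
        write_results_table(points, outdir / "equity_plane.csv")
        paths.append(outdir / "equity_plane.csv")
        ordering = rank_and_select(points)
        (outdir / "priority_ordering.json").write_text(
            json.dumps(
                {
                    "by_nhb": list(ordering.by_nhb),
                    "by_ede": list(ordering.by_ede),
                    "selected_by_nhb": sorted(ordering.selected_by_nhb),
                    "selected_by_ede": sorted(ordering.selected_by_ede),
                    "symmetric_difference": sorted(ordering.symmetric_difference),
                },
                indent=2,
            )
        )
        paths.append(outdir / "priority_ordering.json")
        if config.make_plot:
            plot_equity_plane(points, outdir / "equity_plane.png")

    # --- Stage 4: sensitivity scenarios ----------------------------------
    if config.run_scenarios:
        with _time("sensitivity"):
            suite = run_scenario_suite(
                catalog,
                prevalence,
                uptake,
                baseline,
                analysis,
                DEFAULT_SCENARIOS,
                alt_baselines={"children_only": baselines["children_only"]},
            )
            write_results_table(suite, outdir / "scenario_grid.csv")
            paths.append(outdir / "scenario_grid.csv")
            for res in suite:
                p = outdir / f"equity_plane_{res.scenario}.csv"
                write_results_table(list(res.points), p)
                paths.append(p)

    for p in paths:
        manifest.outputs[p.name] = _sha256(p)
    manifest.write(outdir / "manifest.json")
    return manifest


class _StageTimer:
    def __init__(self, stage: str, manifest: RunManifest):
        self.stage, self.manifest = stage, manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.stage_seconds[self.stage] = time.perf_counter() - self.t0
        return False
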