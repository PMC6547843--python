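"""End-to-end study orchestration.

A run goes: obtain a cohort and measure table (simulated or ingested from
CSV) -> per-measure split-plot ANOVA with post hocs -> build the
standardised and heterogenised replicate designs -> per-measure
strain-by-replicate interaction F under each design -> one-tailed Wilcoxon
comparison of the paired F-ratios.  Every artefact is written under the
output directory together with a manifest (config, seeds, version), and a
re-run with the same config is byte-identical.

Randomness flows through three named seeds — ``cohort`` (animal and time
allocation), ``measures`` (behavioural values), ``heterogenisation`` (the
design draw) — so the subsampling can be replayed independently of the
simulated data, mirroring the separation between the animal study and the
retrospective analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import (
    PostHocComparison,
    SplitPlotResult,
    fit_splitplot,
    fit_splitplot_repeated,
    posthoc_strain_within_time,
)
from .cohort import (
    AnimalRecord,
    MeasureSpec,
    SimulationParams,
    base_measures,
    default_catalogue,
    generate_cohort,
    simulate_measures,
    validate_cohort,
)
from .designs import build_heterogenised, build_standardised, write_assignment
from .prep import TransformSpec
from .repro import compare_designs, fit_strain_by_replicate, strain_difference_ci


class ConfigError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "ingest"
    params: SimulationParams | None = None
    metadata_path: str | None = None
    measures_path: str | None = None
    catalogue: list[MeasureSpec] = field(default_factory=default_catalogue)
    alpha: float = 0.05
    seeds: dict[str, int] = field(
        default_factory=lambda: {"cohort": 0, "measures": 1, "heterogenisation": 2}
    )
    output_dir: str = "phenorep_run"
    trial_error: str = "cage"

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        have_paths = self.metadata_path is not None and self.measures_path is not None
        if self.mode == "simulate" and have_paths:
            raise ConfigError("simulate mode must not set input paths")
        if self.mode == "ingest" and not have_paths:
            raise ConfigError("ingest mode needs metadata_path and measures_path")
        for key in ("cohort", "measures", "heterogenisation"):
            if key not in self.seeds:
                raise ConfigError(f"missing seed {key!r}")


# ---------------------------------------------------------------------------
# Config (de)serialisation


def _spec_to_dict(spec: MeasureSpec) -> dict:
    return {
        "measure_id": spec.measure_id,
        "test": spec.test,
        "transform": {"kind": spec.transform.kind, "offset": spec.transform.offset},
        "repeated": spec.repeated,
        "bounded": list(spec.bounded) if spec.bounded else None,
        "base_id": spec.base_id,
        "trial": spec.trial,
    }


def _spec_from_dict(d: dict) -> MeasureSpec:
    tf = d.get("transform", {"kind": "none", "offset": 0.0})
    return MeasureSpec(
        measure_id=d["measure_id"],
        test=d["test"],
        transform=TransformSpec(tf["kind"], tf.get("offset", 0.0)),
        repeated=d.get("repeated", False),
        bounded=tuple(d["bounded"]) if d.get("bounded") else None,
        base_id=d.get("base_id", ""),
        trial=d.get("trial"),
    )


def config_to_dict(config: RunConfig) -> dict:
    params = None
    if config.params is not None:
        params = dataclasses.asdict(config.params)
        params["dropout"] = list(params["dropout"]) if params["dropout"] else None
    return {
        "mode": config.mode,
        "params": params,
        "metadata_path": config.metadata_path,
        "measures_path": config.measures_path,
        "catalogue": [_spec_to_dict(s) for s in config.catalogue],
        "alpha": config.alpha,
        "seeds": dict(config.seeds),
        "output_dir": str(config.output_dir),
        "trial_error": config.trial_error,
    }


def config_from_dict(d: dict) -> RunConfig:
    params = None
    if d.get("params") is not None:
        p = dict(d["params"])
        p["dropout"] = tuple(p["dropout"]) if p.get("dropout") else None
        params = SimulationParams(**p)
    return RunConfig(
        mode=d.get("mode", "simulate"),
        params=params,
        metadata_path=d.get("metadata_path"),
        measures_path=d.get("measures_path"),
        catalogue=[_spec_from_dict(s) for s in d.get("catalogue", [])]
        or default_catalogue(),
        alpha=d.get("alpha", 0.05),
        seeds=dict(d.get("seeds", {"cohort": 0, "measures": 1, "heterogenisation": 2})),
        output_dir=d.get("output_dir", "phenorep_run"),
        trial_error=d.get("trial_error", "cage"),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Input ingestion and validation


def read_cohort_csv(path) -> list[AnimalRecord]:
    df = pd.read_csv(path)
    required = {"animal_id", "strain", "cage_id", "pair_id", "time_group", "batch", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata CSV missing columns {sorted(missing)}")
    return [
        AnimalRecord(
            animal_id=str(r.animal_id), strain=str(r.strain), cage_id=str(r.cage_id),
            pair_id=int(r.pair_id), time_group=str(r.time_group), batch=int(r.batch),
            present=bool(r.present),
        )
        for r in df.itertuples()
    ]


def read_measures_csv(path) -> pd.DataFrame:
    # round_trip parsing so re-ingesting a written table is bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def validate_inputs(
    cohort: list[AnimalRecord],
    table: pd.DataFrame,
    catalogue: list[MeasureSpec] | None = None,
) -> list[str]:
    """Check design and measure-table invariants; returns all violations."""
    catalogue = catalogue if catalogue is not None else default_catalogue()
    violations = validate_cohort(cohort)
    present = {r.animal_id for r in cohort if r.present}
    required_cols = {"animal_id", "measure_id", "value"}
    missing_cols = required_cols - set(table.columns)
    if missing_cols:
        return violations + [f"measures table missing columns {sorted(missing_cols)}"]
    if table.value.isna().any():
        bad = table[table.value.isna()].animal_id.tolist()[:3]
        violations.append(f"missing values for animal(s) {bad}")
    for spec in base_measures(catalogue):
        rows = table[table.measure_id == spec.base_id]
        expected = 2 if spec.repeated else 1
        counts = rows.groupby("animal_id").size()
        for animal in sorted(present):
            n = int(counts.get(animal, 0))
            if n != expected:
                violations.append(
                    f"measure {spec.base_id!r}: animal {animal} has {n} rows, "
                    f"expected {expected}"
                )
    extra = set(table.animal_id) - {r.animal_id for r in cohort}
    if extra:
        violations.append(f"measure rows for unknown animal(s) {sorted(extra)[:3]}")
    return violations


# ---------------------------------------------------------------------------
# The full run


@dataclass
class RunReport:
    output_dir: Path
    artefacts: dict[str, Path]
    splitplot: list[SplitPlotResult]
    posthocs: dict[str, list[PostHocComparison]]
    comparison: object


def _posthoc_frame(posthocs: dict[str, list[PostHocComparison]]) -> pd.DataFrame:
    rows = [
        vars(c) | {"measure_id": m} for m, comps in posthocs.items() for c in comps
    ]
    cols = ["measure_id", "description", "estimate", "p_raw", "p_holm", "significant", "note"]
    return pd.DataFrame(rows, columns=cols)


def run_study(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artefacts.

    Artefacts under ``config.output_dir``: ``cohort.csv``, ``measures.csv``,
    ``splitplot_results.csv``, ``posthoc_results.csv``,
    ``design_standardised.csv``, ``design_heterogenised.csv``,
    ``paired_f.csv``, ``comparison.json``, ``strain_differences.csv`` and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalogue = config.catalogue

    if config.mode == "simulate":
        params = config.params if config.params is not None else SimulationParams()
        cohort_params = dataclasses.replace(params, seed=config.seeds["cohort"])
        measure_params = dataclasses.replace(params, seed=config.seeds["measures"])
        cohort = generate_cohort(cohort_params)
        table = simulate_measures(cohort, measure_params, catalogue)
    else:
        cohort = read_cohort_csv(config.metadata_path)
        table = read_measures_csv(config.measures_path)

    violations = validate_inputs(cohort, table, catalogue)
    if violations:
        raise ValidationError("; ".join(violations))

    artefacts: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artefacts[name] = path

    write_csv("cohort.csv", pd.DataFrame([vars(r) for r in cohort]))
    write_csv("measures.csv", table)

    # Per-measure split-plot ANOVA (+ post hocs where the interaction is
    # significant at alpha).
    results: list[SplitPlotResult] = []
    posthocs: dict[str, list[PostHocComparison]] = {}
    for spec in base_measures(catalogue):
        if spec.repeated:
            res = fit_splitplot_repeated(
                table, cohort, spec, config.alpha, trial_error=config.trial_error
            )
        else:
            res = fit_splitplot(table, cohort, spec, config.alpha)
        results.append(res)
        inter = res.term("time:strain")
        if not res.flagged and inter.p_value == inter.p_value and inter.p_value < config.alpha:
            posthocs[res.measure_id] = posthoc_strain_within_time(
                res, table, cohort, spec, config.alpha
            )
    write_csv("splitplot_results.csv", pd.concat([r.to_frame() for r in results], ignore_index=True))
    write_csv("posthoc_results.csv", _posthoc_frame(posthocs))

    # Replicate designs and paired interaction F-ratios over the full
    # catalogue (trial entries of repeated measures count separately).
    std = build_standardised(cohort)
    het = build_heterogenised(cohort, config.seeds["heterogenisation"])
    write_assignment(std, out / "design_standardised.csv")
    write_assignment(het, out / "design_heterogenised.csv")
    artefacts["design_standardised.csv"] = out / "design_standardised.csv"
    artefacts["design_heterogenised.csv"] = out / "design_heterogenised.csv"

    f_std = [fit_strain_by_replicate(table, std, cohort, m) for m in catalogue]
    f_het = [fit_strain_by_replicate(table, het, cohort, m) for m in catalogue]
    comparison = compare_designs(f_std, f_het)
    write_csv(
        "paired_f.csv",
        pd.DataFrame(comparison.paired_f, columns=["measure_id", "f_standardised", "f_heterogenised"]),
    )

    ci_rows = []
    for design in (std, het):
        for m in catalogue:
            for k in (1, 2, 3):
                ci = strain_difference_ci(table, design, cohort, m, k)
                ci_rows.append(vars(ci) | {"design_type": design.design_type})
    write_csv("strain_differences.csv", pd.DataFrame(ci_rows))

    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artefacts["comparison.json"] = out / "comparison.json"

    manifest = {
        "config": config_to_dict(config),
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artefacts["manifest.json"] = out / "manifest.json"

    return RunReport(out, artefacts, results, posthocs, comparison)
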