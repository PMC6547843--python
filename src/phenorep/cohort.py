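"""Synthetic split-plot phenotyping cohorts.

The study design being emulated: two inbred mouse strains (C57BL/6J, "B6";
DBA/2N, "D2") housed in same-strain cages of three animals, eight cages per
strain.  Cages form matched B6/D2 pairs that share a rack microenvironment
and are always tested on the same day in the same daily time window.  Within
every cage, the three animals are randomly assigned one each to the three
testing-time groups (morning, noon, afternoon) — a classical split-plot
design with strain varying between cages (whole plots) and testing time
within cages (sub-plots).

Behavioural measures are generated from the linear model the downstream
ANOVA assumes,

    y = mu_m + delta_{m,t} * s + tau_{m,t} + c_cage + a_animal + theta_m * 1[trial 2] + eps,

with strain coded s = +1/2 (B6) / -1/2 (D2) so that ``delta`` is directly
the B6 - D2 mean contrast at testing time ``t``; ``c`` is a cage effect
drawn once per cage per measure, ``a`` an animal effect for repeated
(two-trial) measures, and ``eps`` the residual.  Values are generated on
the analysis (transformed) scale; a raw-scale column is derived through the
inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prep import TransformSpec, inverse_transform

STRAINS = ("B6", "D2")
TIME_GROUPS = ("morning", "noon", "afternoon")
TESTS = ("EPM", "DL", "OF", "FE", "LM")

#: Strain contrast coding: delta is the B6 - D2 difference.
STRAIN_CODE = {"B6": 0.5, "D2": -0.5}


class ParameterError(ValueError):
    """Invalid simulation parameters."""


class CohortError(ValueError):
    """A cohort violates the split-plot design invariants."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's design coordinates."""

    animal_id: str
    strain: str
    cage_id: str
    pair_id: int
    time_group: str
    batch: int
    present: bool = True


@dataclass(frozen=True)
class MeasureSpec:
    """One behavioural measure (one of the study's 20 readouts).

    Repeated (labyrinth-maze) readouts come in trial pairs: the two
    catalogue entries for e.g. maze errors share ``base_id`` and differ in
    ``trial``; rows in the measure table carry the ``base_id`` with an
    explicit trial column.
    """

    measure_id: str
    test: str
    transform: TransformSpec = TransformSpec("none")
    repeated: bool = False
    bounded: tuple[float, float] | None = None
    base_id: str = ""
    trial: int | None = None

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if not self.base_id:
            object.__setattr__(self, "base_id", self.measure_id)
        if self.repeated and self.trial not in (1, 2):
            raise ValueError("repeated measure entries need trial 1 or 2")


def default_catalogue() -> list[MeasureSpec]:
    """The default 20-measure catalogue.

    Six elevated-plus-maze (EPM), three dark-light (DL), four open-field
    (OF) and three free-exploration (FE) measures, plus the labyrinth-maze
    (LM) error count and exit time at each of two trials.  The catalogue is
    replaceable through the run configuration; transforms follow common
    practice for each measure type (angular for proportions, square root
    for counts, log for latencies) and are provisional defaults.
    """
    ang = TransformSpec("angular")
    sqrt = TransformSpec("sqrt")
    log1 = TransformSpec("log", offset=1.0)
    unit = (0.0, 1.0)
    cat = [
        MeasureSpec("epm_rel_open_time", "EPM", ang, bounded=unit),
        MeasureSpec("epm_rel_open_entries", "EPM", ang, bounded=unit),
        MeasureSpec("epm_rel_open_distance", "EPM", ang, bounded=unit),
        MeasureSpec("epm_total_arm_entries", "EPM", sqrt, bounded=(0, np.inf)),
        MeasureSpec("epm_total_distance", "EPM", sqrt, bounded=(0, np.inf)),
        MeasureSpec("epm_protected_head_dips", "EPM", sqrt, bounded=(0, np.inf)),
        MeasureSpec("dl_latency_to_light", "DL", log1, bounded=(0, np.inf)),
        MeasureSpec("dl_time_in_light", "DL", sqrt, bounded=(0, np.inf)),
        MeasureSpec("dl_entries_into_light", "DL", sqrt, bounded=(0, np.inf)),
        MeasureSpec("of_centre_time", "OF", sqrt, bounded=(0, np.inf)),
        MeasureSpec("of_centre_entries", "OF", sqrt, bounded=(0, np.inf)),
        MeasureSpec("of_centre_distance", "OF", sqrt, bounded=(0, np.inf)),
        MeasureSpec("of_total_distance", "OF", sqrt, bounded=(0, np.inf)),
        MeasureSpec("fe_latency_to_enter", "FE", log1, bounded=(0, np.inf)),
        MeasureSpec("fe_excursions", "FE", sqrt, bounded=(0, np.inf)),
        MeasureSpec("fe_time_in_arena", "FE", sqrt, bounded=(0, np.inf)),
    ]
    for base, tf in (("lm_errors", sqrt), ("lm_exit_time", log1)):
        for trial in (1, 2):
            cat.append(
                MeasureSpec(
                    f"{base}_t{trial}",
                    "LM",
                    tf,
                    repeated=True,
                    bounded=(0, np.inf),
                    base_id=base,
                    trial=trial,
                )
            )
    return cat


def base_measures(catalogue: list[MeasureSpec]) -> list[MeasureSpec]:
    """One representative spec per base measure (trial entries collapsed)."""
    seen: dict[str, MeasureSpec] = {}
    for spec in catalogue:
        seen.setdefault(spec.base_id, spec)
    return list(seen.values())


@dataclass
class SimulationParams:
    """Generative-model parameters, keyed by base measure id.

    ``strain_effect_by_time`` holds the B6 - D2 contrast delta at each
    testing time; a time-varying delta is what makes strain differences
    non-reproducible across testing times.  Standard deviations are shared
    across measures (the analysis scale is standardised per measure).
    """

    grand_mean: dict[str, float] = field(default_factory=dict)
    strain_effect_by_time: dict[str, dict[str, float]] = field(default_factory=dict)
    time_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    trial_effect: dict[str, float] = field(default_factory=dict)
    cage_sd: float = 0.5
    residual_sd: float = 1.0
    animal_sd: float = 0.5
    n_pairs_per_time: int = 8
    dropout: tuple[str, str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.cage_sd, self.animal_sd) < 0 or self.residual_sd <= 0:
            raise ParameterError("sds must be >= 0 and residual_sd > 0")
        if self.n_pairs_per_time < 1:
            raise ParameterError("n_pairs_per_time must be >= 1")
        if self.dropout is not None:
            strain, time_group = self.dropout
            if strain not in STRAINS or time_group not in TIME_GROUPS:
                raise ParameterError(f"invalid dropout {self.dropout!r}")


# Default effect sizes (analysis-scale units, residual_sd = 1): a large
# strain contrast (|delta| = 1.8) present in the morning and noon windows
# but absent in the afternoon for the state-anxiety tests, and a constant
# contrast for the trait-anxiety (free-exploration) test.
DEFAULT_DELTA = 1.8
DEFAULT_TIME_EFFECT = {"morning": 0.4, "noon": 0.0, "afternoon": -0.4}


def default_params(
    seed: int = 0,
    catalogue: list[MeasureSpec] | None = None,
    *,
    delta: float = DEFAULT_DELTA,
    constant_delta: bool = False,
    dropout: tuple[str, str] | None = None,
) -> SimulationParams:
    """Study-condition defaults for the generative model.

    State-type measures (EPM, DL, OF, LM) get a time-dependent strain
    contrast (present morning and noon, absent in the afternoon); the
    trait-type FE measures get a time-constant contrast.  With
    ``constant_delta=True`` every measure gets the same contrast at all
    three times — the null configuration for the strain-by-time
    interaction.
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    # Plausible analysis-scale centres per transform kind.
    centre = {"angular": 0.6, "sqrt": 3.0, "log": 2.5, "none": 10.0, "inverse": 0.5}
    params = SimulationParams(seed=seed, dropout=dropout)
    for i, spec in enumerate(base_measures(catalogue)):
        # Alternate contrast sign across measures: anxiety-type readouts run
        # D2 > B6, locomotion-type readouts B6 > D2; the sign is irrelevant
        # to every F statistic.
        d = delta if i % 2 == 0 else -delta
        if constant_delta or spec.test == "FE":
            by_time = {t: d for t in TIME_GROUPS}
        else:
            by_time = {"morning": d, "noon": d, "afternoon": 0.0}
        params.grand_mean[spec.base_id] = centre[spec.transform.kind]
        params.strain_effect_by_time[spec.base_id] = by_time
        params.time_effect[spec.base_id] = (
            dict(DEFAULT_TIME_EFFECT)
            if spec.test != "FE"
            else {t: 0.0 for t in TIME_GROUPS}
        )
        if spec.repeated:
            params.trial_effect[spec.base_id] = -0.5
    return params


def reference_study_params(seed: int = 0, **kwargs) -> SimulationParams:
    """Defaults plus the deposited study's single dropout (DBA/2N, afternoon)."""
    return default_params(seed=seed, dropout=("D2", "afternoon"), **kwargs)


def generate_cohort(params: SimulationParams) -> list[AnimalRecord]:
    """Generate the split-plot cohort.

    Returns ``n_pairs_per_time`` matched cage pairs, each cage holding three
    animals with the three time groups randomly permuted over its animal
    slots, and pairs split evenly over two batches.  With the default eight
    pairs the cohort has 48 animals in 16 cages.  If ``dropout`` is set,
    exactly one animal of that strain and time group is marked absent.
    All randomisation is driven by ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 0xC0])
    n_pairs = params.n_pairs_per_time
    half = n_pairs // 2
    batches = np.array([1] * (n_pairs - half) + [2] * half)
    rng.shuffle(batches)
    records: list[AnimalRecord] = []
    for pair in range(1, n_pairs + 1):
        for strain in STRAINS:
            cage_id = f"{strain}_c{pair:02d}"
            times = list(rng.permutation(TIME_GROUPS))
            for slot, time_group in enumerate(times, start=1):
                records.append(
                    AnimalRecord(
                        animal_id=f"{cage_id}_m{slot}",
                        strain=strain,
                        cage_id=cage_id,
                        pair_id=pair,
                        time_group=time_group,
                        batch=int(batches[pair - 1]),
                    )
                )
    if params.dropout is not None:
        strain, time_group = params.dropout
        candidates = [
            i
            for i, r in enumerate(records)
            if r.strain == strain and r.time_group == time_group
        ]
        drop = candidates[rng.integers(len(candidates))]
        records[drop] = replace(records[drop], present=False)
    return records


def cohort_frame(cohort: list[AnimalRecord]) -> pd.DataFrame:
    """Cohort as a tidy metadata table (one row per animal)."""
    return pd.DataFrame([vars(r) for r in cohort])


def validate_cohort(cohort: list[AnimalRecord]) -> list[str]:
    """Check the split-plot invariants; returns a list of violations."""
    violations: list[str] = []
    df = cohort_frame(cohort)
    if df.animal_id.duplicated().any():
        violations.append("duplicate animal_id")
    for cage, sub in df.groupby("cage_id"):
        if sub.strain.nunique() != 1:
            violations.append(f"cage {cage}: mixed strains")
        if sorted(sub.time_group) != sorted(TIME_GROUPS):
            violations.append(f"cage {cage}: time groups {list(sub.time_group)}")
    for pair, sub in df.groupby("pair_id"):
        cages = sub.groupby("cage_id").strain.first()
        if len(cages) != 2 or set(cages) != set(STRAINS):
            violations.append(f"pair {pair}: needs one cage per strain")
        if sub.batch.nunique() != 1:
            violations.append(f"pair {pair}: batches differ within pair")
    return violations


def _measure_rng(params: SimulationParams, index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, 0xDA, index])


def simulate_measures(
    cohort: list[AnimalRecord],
    params: SimulationParams,
    catalogue: list[MeasureSpec] | None = None,
) -> pd.DataFrame:
    """Simulate the measure table for every present animal.

    Returns a long-format table with columns ``animal_id``, ``measure_id``
    (the base measure id), ``trial`` (1/2 for repeated measures, NA
    otherwise), ``value`` (analysis scale) and ``raw_value`` (inverse
    transform, clipped to the measure's bounds).  Fully deterministic given
    ``params`` and the cohort.
    """
    params.validate()
    catalogue = catalogue if catalogue is not None else default_catalogue()
    if not catalogue:
        raise ParameterError("catalogue is empty")
    violations = validate_cohort(cohort)
    if violations:
        raise CohortError("; ".join(violations))
    present = [r for r in cohort if r.present]
    cages = sorted({r.cage_id for r in cohort})
    cage_index = {c: i for i, c in enumerate(cages)}
    frames = []
    for m_index, spec in enumerate(sorted(base_measures(catalogue), key=lambda s: s.base_id)):
        rng = _measure_rng(params, m_index)
        mu = params.grand_mean.get(spec.base_id, 0.0)
        delta = params.strain_effect_by_time.get(spec.base_id, {})
        tau = params.time_effect.get(spec.base_id, {})
        cage_eff = rng.normal(0.0, params.cage_sd, size=len(cages))
        n_trials = 2 if spec.repeated else 1
        theta = params.trial_effect.get(spec.base_id, 0.0)
        animal_eff = (
            rng.normal(0.0, params.animal_sd, size=len(present))
            if spec.repeated
            else np.zeros(len(present))
        )
        for trial in range(1, n_trials + 1):
            fixed = np.array(
                [
                    mu
                    + delta.get(r.time_group, 0.0) * STRAIN_CODE[r.strain]
                    + tau.get(r.time_group, 0.0)
                    for r in present
                ]
            )
            value = (
                fixed
                + cage_eff[[cage_index[r.cage_id] for r in present]]
                + animal_eff
                + (theta if trial == 2 else 0.0)
                + rng.normal(0.0, params.residual_sd, size=len(present))
            )
            raw = inverse_transform(value, spec.transform)
            if spec.bounded is not None:
                raw = np.clip(raw, *spec.bounded)
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": [r.animal_id for r in present],
                        "measure_id": spec.base_id,
                        "trial": float(trial) if spec.repeated else np.nan,
                        "value": value,
                        "raw_value": raw,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def measure_values(
    table: pd.DataFrame, spec: MeasureSpec, column: str = "value"
) -> pd.Series:
    """Values for one catalogue entry, indexed by animal.

    For a repeated measure's trial entry this selects that trial's rows, so
    each of the 20 catalogue measures yields one value per animal.
    ``column`` selects the analysis scale (``value``, default) or the raw
    scale (``raw_value``).
    """
    rows = table[table.measure_id == spec.base_id]
    if spec.trial is not None:
        rows = rows[rows.trial == spec.trial]
    return pd.Series(rows[column].to_numpy(), index=rows.animal_id.to_numpy())
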