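"""Standardised and heterogenised pseudo-replicate experiments.

The retrospective reproducibility analysis re-partitions the cohort into
three replicate "experiments" under two designs.  The sampling unit is the
matched animal pair: cage pair ``p`` tested at time ``t`` contributes the
unit ``(p, t)`` — one B6 and one D2 animal tested on the same day in the
same window.  With 8 cage pairs and 3 times there are 24 such units.

* standardised: each replicate is one whole testing-time group — all
  animals within a replicate share the same daily testing time, exactly as
  three conventionally standardised experiments would.
* heterogenised: each replicate draws a balanced random selection of units
  from exactly two testing times (replicate 1 mixes morning+noon, 2
  noon+afternoon, 3 afternoon+morning), so time-of-day variation is folded
  into every replicate.  Every unit is used exactly once.

Designs can be written to and re-loaded from CSV so that a specific
documented draw can be replayed and validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import TIME_GROUPS, AnimalRecord, cohort_frame

#: Cyclic pairing of time groups into heterogenised replicates: the only
#: symmetric scheme in which every time group feeds exactly two replicates.
CYCLIC_MIX = (
    ("morning", "noon"),
    ("noon", "afternoon"),
    ("afternoon", "morning"),
)


class DesignError(ValueError):
    """The cohort cannot support the requested replicate design."""


class DesignValidationError(ValueError):
    """A loaded assignment violates a replicate-design invariant."""


@dataclass
class ReplicateDesign:
    """Assignment of (pair_id, time_group) units to three replicates."""

    design_type: str  # "standardised" | "heterogenised"
    replicates: list[list[tuple[int, str]]]
    seed: int | None = None
    mixes: tuple = field(default=CYCLIC_MIX)

    def units(self) -> list[tuple[int, str]]:
        return [u for rep in self.replicates for u in rep]

    def animals(self, cohort: list[AnimalRecord]) -> pd.DataFrame:
        """Per-animal view: cohort metadata plus a ``replicate`` column."""
        meta = cohort_frame(cohort)
        meta = meta[meta.present]
        lookup = {
            unit: k for k, rep in enumerate(self.replicates, start=1) for unit in rep
        }
        keys = list(zip(meta.pair_id, meta.time_group))
        mask = [k in lookup for k in keys]
        out = meta[mask].copy()
        out["replicate"] = [lookup[k] for k, m in zip(keys, mask) if m]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": p,
                "time_group": t,
                "replicate_index": k,
                "design_type": self.design_type,
            }
            for k, rep in enumerate(self.replicates, start=1)
            for p, t in rep
        ]
        return pd.DataFrame(rows).sort_values(
            ["replicate_index", "time_group", "pair_id"], ignore_index=True
        )


def _complete_units(cohort: list[AnimalRecord]) -> set[tuple[int, str]]:
    """Units with both matched animals present."""
    meta = cohort_frame(cohort)
    counts = meta[meta.present].groupby(["pair_id", "time_group"]).size()
    return {k for k, n in counts.items() if n == 2}


def build_standardised(cohort: list[AnimalRecord]) -> ReplicateDesign:
    """The three testing-time groups, verbatim, as three replicates.

    Deterministic; a dropout simply leaves one replicate an animal short
    (the unit stays in the design with its unmatched animal).
    """
    meta = cohort_frame(cohort)
    present_times = set(meta[meta.present].time_group)
    if present_times != set(TIME_GROUPS):
        raise DesignError(
            f"cohort covers time groups {sorted(present_times)}, "
            f"need all of {list(TIME_GROUPS)}"
        )
    units = meta[meta.present].groupby(["pair_id", "time_group"]).size().index
    replicates = [
        sorted((int(p), str(t)) for p, t in units if t == tg) for tg in TIME_GROUPS
    ]
    return ReplicateDesign("standardised", replicates)


def build_heterogenised(cohort: list[AnimalRecord], seed: int) -> ReplicateDesign:
    """Random balanced two-time mixtures, every complete pair used once.

    Each time group's complete units are split (seed-driven) between the
    two replicates that mix that time; with 8 pairs per time the split is
    4+4.  Incomplete units (a dropout's unmatched animal) are excluded —
    the analysis unit is the matched pair.
    """
    units = _complete_units(cohort)
    per_time = {tg: sorted(int(p) for p, t in units if t == tg) for tg in TIME_GROUPS}
    shortfall = {tg: n for tg, n in ((tg, len(v)) for tg, v in per_time.items()) if n < 2}
    if shortfall:
        raise DesignError(f"need >= 2 complete pairs per time group, got {shortfall}")
    rng = np.random.default_rng([seed, 0x8E])
    # Replicate r mixes times CYCLIC_MIX[r]; each time feeds two replicates.
    takes: dict[tuple[str, int], list[int]] = {}
    for tg in TIME_GROUPS:
        pool = np.array(per_time[tg])
        rng.shuffle(pool)
        first, second = [r for r, mix in enumerate(CYCLIC_MIX) if tg in mix]
        n = len(pool)
        n_first = n // 2 + (rng.integers(2) if n % 2 else 0)
        takes[(tg, first)] = sorted(int(p) for p in pool[:n_first])
        takes[(tg, second)] = sorted(int(p) for p in pool[n_first:])
    replicates = []
    for r, mix in enumerate(CYCLIC_MIX):
        rep = [(p, tg) for tg in mix for p in takes[(tg, r)]]
        replicates.append(sorted(rep))
    return ReplicateDesign("heterogenised", replicates, seed=seed)


def validate_design(
    design: ReplicateDesign, cohort: list[AnimalRecord] | None = None
) -> None:
    """Check every replicate-design invariant; raise on the first violation."""
    if design.design_type not in ("standardised", "heterogenised"):
        raise DesignValidationError(f"unknown design_type {design.design_type!r}")
    if len(design.replicates) != 3:
        raise DesignValidationError(
            f"need exactly 3 replicates, got {len(design.replicates)}"
        )
    units = design.units()
    if len(set(units)) != len(units):
        dup = pd.Series(units).loc[pd.Series(units).duplicated()].iloc[0]
        raise DesignValidationError(f"unit {dup} appears in more than one replicate")
    for k, rep in enumerate(design.replicates, start=1):
        times = {t for _, t in rep}
        if design.design_type == "standardised" and len(times) != 1:
            raise DesignValidationError(
                f"standardised replicate {k} mixes time groups {sorted(times)}"
            )
        if design.design_type == "heterogenised" and len(times) != 2:
            raise DesignValidationError(
                f"heterogenised replicate {k} spans {sorted(times)}, need exactly 2"
            )
    if cohort is not None:
        meta = cohort_frame(cohort)
        cohort_units = set(
            meta[meta.present].groupby(["pair_id", "time_group"]).size().index
        )
        expected = (
            cohort_units
            if design.design_type == "standardised"
            else _complete_units(cohort)
        )
        if set(units) != expected:
            missing = sorted(expected - set(units))[:3]
            extra = sorted(set(units) - expected)[:3]
            raise DesignValidationError(
                f"unit partition mismatch: missing {missing}, unknown {extra}"
            )


def write_assignment(design: ReplicateDesign, path) -> None:
    """Deterministic CSV writer (audit trail for a specific draw)."""
    design.to_frame().to_csv(path, index=False)


def load_assignment(path) -> ReplicateDesign:
    """Parse an assignment CSV and validate it against all invariants."""
    df = pd.read_csv(path)
    required = {"pair_id", "time_group", "replicate_index", "design_type"}
    if not required.issubset(df.columns):
        raise DesignValidationError(
            f"assignment file needs columns {sorted(required)}"
        )
    kinds = df.design_type.unique()
    if len(kinds) != 1:
        raise DesignValidationError(f"mixed design_type values {list(kinds)}")
    reps = sorted(df.replicate_index.unique())
    if reps != [1, 2, 3]:
        raise DesignValidationError(f"replicate_index values {reps}, need [1, 2, 3]")
    replicates = [
        sorted(
            (int(r.pair_id), str(r.time_group))
            for r in df[df.replicate_index == k].itertuples()
        )
        for k in (1, 2, 3)
    ]
    design = ReplicateDesign(str(kinds[0]), replicates)
    validate_design(design)
    return design
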