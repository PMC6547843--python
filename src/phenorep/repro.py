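"""Between-replicate reproducibility statistics.

Reproducibility of a strain difference across replicate experiments is
quantified by the strain-by-replicate interaction of a fixed-effects
two-way ANOVA (2 strains x 3 replicates): the interaction F measures how
much the strain contrast varies between replicates relative to residual
noise, so a *lower* F means *better* reproducibility.

Per measure, the interaction F is computed once under the standardised and
once under the heterogenised design, and the 20 paired F-ratios are then
compared with a one-tailed Wilcoxon signed-rank test of the directional
hypothesis "heterogenised F < standardised F".  The signed-rank statistic
is computed with midranks for ties and zero differences discarded; the
default large-sample normal approximation (tie-corrected, no continuity
correction) is complemented by an exact-enumeration mode.

Descriptive per-replicate strain differences (B6 - D2 means with pooled-t
95% confidence intervals) are computed on the raw scale to ease
interpretation; F-ratios use the analysis (transformed) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import DegenerateInputError, _sum_contrast, type3_ss
from .cohort import STRAINS, AnimalRecord, MeasureSpec, measure_values
from .designs import ReplicateDesign

NAN = float("nan")


class UndefinedTestError(ValueError):
    """The signed-rank test is undefined (no non-zero differences)."""


@dataclass(frozen=True)
class InteractionF:
    """Strain-by-replicate interaction F for one measure under one design."""

    measure_id: str
    design_type: str
    f: float
    df_num: int
    df_den: int


@dataclass(frozen=True)
class StrainDifference:
    """Descriptive B6 - D2 mean difference within one replicate."""

    measure_id: str
    replicate_index: int
    mean_diff: float
    ci_low: float
    ci_high: float
    n_b6: int
    n_d2: int
    note: str = ""


@dataclass
class DesignComparison:
    """Paired-F Wilcoxon verdict comparing the two designs."""

    paired_f: list[tuple[str, float, float]]
    w_statistic: float
    z: float
    p_one_tailed: float
    n_effective: int
    method: str

    def to_json_dict(self) -> dict:
        return {
            "w_statistic": self.w_statistic,
            "z": self.z,
            "p_one_tailed": self.p_one_tailed,
            "n_effective": self.n_effective,
            "method": self.method,
        }


def _design_values(
    table: pd.DataFrame,
    design: ReplicateDesign,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    column: str = "value",
) -> pd.DataFrame:
    animals = design.animals(cohort)
    vals = measure_values(table, measure, column=column)
    out = animals.assign(value=vals.reindex(animals.animal_id).to_numpy())
    if out.value.isna().any():
        missing = out[out.value.isna()].animal_id.tolist()[:3]
        raise DegenerateInputError(
            f"no value for animal(s) {missing} in measure {measure.measure_id!r}"
        )
    return out


def fit_strain_by_replicate(
    table: pd.DataFrame,
    design: ReplicateDesign,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
) -> InteractionF:
    """Two-way fixed-effects ANOVA; returns the interaction term's F.

    Strain and replicate experiment are both fixed; sums of squares are
    Type III so the single-dropout imbalance is handled as in the
    per-measure model.  df = (2, N - 6) for N animals in the design.
    """
    df = _design_values(table, design, cohort, measure)
    cells = df.groupby(["strain", "replicate"]).size()
    if len(cells) < 2 * len(design.replicates) or (cells < 1).any():
        raise DegenerateInputError(
            f"empty strain x replicate cell in {measure.measure_id!r}"
        )
    y = df.value.to_numpy(dtype=float)
    s = _sum_contrast(df.strain.to_numpy(), list(STRAINS))
    r = _sum_contrast(df.replicate.to_numpy(), sorted(df.replicate.unique()))
    inter = np.hstack([r * s[:, [0]]])
    blocks = {"strain": s, "replicate": r, "strain:replicate": inter}
    ss, rss, df_resid = type3_ss(y, blocks)
    df_num = inter.shape[1]
    ms_resid = rss / df_resid if df_resid else NAN
    f = (ss["strain:replicate"] / df_num) / ms_resid if ms_resid > 0 else NAN
    return InteractionF(measure.measure_id, design.design_type, float(f), df_num, df_resid)


def strain_difference_ci(
    table: pd.DataFrame,
    design: ReplicateDesign,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    replicate_index: int,
    level: float = 0.95,
    column: str = "raw_value",
) -> StrainDifference:
    """B6 - D2 mean difference in one replicate with a pooled-t interval.

    Defaults to the raw (untransformed) scale for descriptive display.
    """
    df = _design_values(table, design, cohort, measure, column=column)
    df = df[df.replicate == replicate_index]
    g1 = df[df.strain == STRAINS[0]].value.to_numpy()
    g2 = df[df.strain == STRAINS[1]].value.to_numpy()
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return StrainDifference(
            measure.measure_id, replicate_index,
            float(g1.mean() - g2.mean()) if n1 and n2 else NAN,
            NAN, NAN, n1, n2, note="fewer than 2 animals in a strain group",
        )
    diff = float(g1.mean() - g2.mean())
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    tcrit = float(stats.t.ppf(0.5 + level / 2, n1 + n2 - 2))
    return StrainDifference(
        measure.measure_id, replicate_index, diff,
        diff - tcrit * se, diff + tcrit * se, n1, n2,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank engine


def _signed_rank_stats(d: np.ndarray) -> tuple[float, np.ndarray, int]:
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    return w, ranks, n


def signed_rank_normal(d) -> tuple[float, float, float, int]:
    """Tie-corrected normal approximation, one-tailed (negative shift).

    W is the sum of ranks of the positive differences (midranks for ties,
    zeros discarded).  Z = (W - n(n+1)/4) / sd with the tie-corrected
    variance n(n+1)(2n+1)/24 - sum(t^3 - t)/48; no continuity correction.
    One-tailed p = Phi(Z) for the alternative "differences tend negative".
    """
    w, ranks, n = _signed_rank_stats(d)
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48).sum())
    if var <= 0:
        raise UndefinedTestError("zero variance (all ranks tied at one value)")
    z = (w - mu) / math.sqrt(var)
    return w, z, float(stats.norm.cdf(z)), n


def signed_rank_exact(d) -> tuple[float, float, float, int]:
    """Exact one-tailed p by enumerating the null sign-flip distribution.

    The null distribution of W is built by dynamic programming over the
    (doubled, hence integer) midranks — equivalent to full enumeration of
    the 2^n sign assignments but polynomial-time.  Returned z is the
    tie-corrected normal deviate for reference.
    """
    w, ranks, n = _signed_rank_stats(d)
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w))
    p = float(dist[: w2 + 1].sum())
    _, z, _, _ = signed_rank_normal(d)
    return w, z, p, n


def compare_designs(
    f_std: list[InteractionF],
    f_het: list[InteractionF],
    method: str = "normal",
) -> DesignComparison:
    """Paired one-tailed Wilcoxon test of "heterogenised F < standardised F".

    The alternative's direction is fixed a priori (the heterogenised design
    is hypothesised to be *more* reproducible, i.e. to have lower
    strain-by-replicate interaction F-ratios); there is deliberately no
    switch to flip it after the fact.  ``method`` is ``normal`` (default),
    ``exact``, or ``auto`` (exact for 12 or fewer non-zero differences).
    """
    if method not in ("normal", "exact", "auto"):
        raise ValueError(f"unknown method {method!r}")
    std = {x.measure_id: x.f for x in f_std}
    het = {x.measure_id: x.f for x in f_het}
    if set(std) != set(het):
        raise ValueError("the two designs cover different measure sets")
    if len(std) < 5:
        raise ValueError(f"need >= 5 measures, got {len(std)}")
    ids = sorted(std)
    d = np.array([het[m] - std[m] for m in ids])
    n_eff = int((d != 0).sum())
    if method == "auto":
        method = "exact" if n_eff <= 12 else "normal"
    engine = signed_rank_exact if method == "exact" else signed_rank_normal
    w, z, p, n_eff = engine(d)
    return DesignComparison(
        paired_f=[(m, std[m], het[m]) for m in ids],
        w_statistic=w, z=z, p_one_tailed=p, n_effective=n_eff, method=method,
    )
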