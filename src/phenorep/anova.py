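"""Split-plot mixed ANOVA with expected-mean-squares F-tests.

The model: strain and testing time are fixed factors, cage is a random
factor nested within strain.  Because every cage holds one animal per time
group, the design is a classical split-plot with two error strata —

* whole-plot (between cages): strain is tested against cage-within-strain;
* sub-plot (within cages): time and the time-by-strain interaction are
  tested against the within-cage residual.

The model is fitted by stratified least squares rather than iterative REML:
for a balanced split-plot the two coincide, the stratified fit is exactly
deterministic, its degrees of freedom are the textbook ones (e.g. df =
(2, 27) for the interaction with 47 animals), and it can be verified
against a hand-computed sums-of-squares partition.  Under imbalance (a
single dropout) each term's sum of squares is Type III: the increase in
residual sum of squares from dropping that term's sum-coded columns from
the full model.

A repeated-measures variant adds the within-animal stratum for the
two-trial labyrinth-maze measures, and Holm-adjusted post hoc contrasts
with partial eta squared effect sizes complete the per-measure analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import (
    STRAINS,
    TIME_GROUPS,
    AnimalRecord,
    MeasureSpec,
    cohort_frame,
    measure_values,
)
from .prep import TransformSpec

NAN = float("nan")


class DegenerateInputError(ValueError):
    """Design or data too degenerate to fit (empty cage, missing values...)."""


class IncompleteRepeatedError(ValueError):
    """A present animal is missing one of the two trials."""


@dataclass(frozen=True)
class TermResult:
    """One ANOVA term: sums of squares, F against its stratum error."""

    term: str
    ss: float
    df: int
    ms: float
    f: float
    df_den: int
    p_value: float
    eta_sq_partial: float


@dataclass
class SplitPlotResult:
    measure_id: str
    terms: list[TermResult]
    residual_df_subplot: int
    transform_used: TransformSpec
    n_animals: int
    flagged: bool = False
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(t) | {"measure_id": self.measure_id} for t in self.terms]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PostHocComparison:
    description: str
    estimate: float
    p_raw: float
    p_holm: float
    significant: bool
    note: str = ""


# ---------------------------------------------------------------------------
# Design-matrix helpers (sum-to-zero coding, Type III drop-term SS)


def _sum_contrast(labels: np.ndarray, levels: list) -> np.ndarray:
    """n x (k-1) sum-to-zero contrast columns for a factor."""
    k = len(levels)
    out = np.zeros((len(labels), k - 1))
    index = {lev: j for j, lev in enumerate(levels)}
    for i, lab in enumerate(labels):
        j = index[lab]
        if j < k - 1:
            out[i, j] = 1.0
        else:
            out[i, :] = -1.0
    return out


def _nested_contrast(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Sum-coded columns for ``inner`` nested within each ``outer`` level."""
    cols = []
    for lev in sorted(set(outer)):
        mask = outer == lev
        inner_levels = sorted(set(inner[mask]))
        block = np.zeros((len(outer), len(inner_levels) - 1))
        block[mask] = _sum_contrast(inner[mask], inner_levels)
        cols.append(block)
    return np.hstack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def type3_ss(
    y: np.ndarray, blocks: dict[str, np.ndarray], *, intercept: bool = True
) -> tuple[dict[str, float], float, int]:
    """Type III sum of squares per block, residual SS and residual df.

    Each block's SS is the residual increase from removing its (sum-coded)
    columns from the full model; on balanced data this equals the
    sequential decomposition.
    """
    parts = [np.ones((len(y), 1))] if intercept else []
    parts += list(blocks.values())
    x_full = np.hstack(parts)
    rss_full, rank_full = _rss(x_full, y)
    ss: dict[str, float] = {}
    for name in blocks:
        parts = [np.ones((len(y), 1))] if intercept else []
        parts += [b for other, b in blocks.items() if other != name]
        if name == "__intercept__":
            parts = [b for other, b in blocks.items() if other != name]
        x_red = np.hstack(parts) if parts else np.zeros((len(y), 0))
        rss_red, _ = _rss(x_red, y) if x_red.shape[1] else (float(y @ y), 0)
        ss[name] = max(rss_red - rss_full, 0.0)
    return ss, rss_full, len(y) - rank_full


def _f_term(
    name: str, ss: float, df: int, ms_den: float, ss_den: float, df_den: int
) -> TermResult:
    ms = ss / df if df else NAN
    if ms_den > 0 and df > 0:
        f = ms / ms_den
        p = float(stats.f.sf(f, df, df_den))
    else:
        f, p = NAN, NAN
    denom = ss + ss_den
    eta = ss / denom if denom > 0 else NAN
    return TermResult(name, ss, df, ms, f, df_den, p, eta)


# ---------------------------------------------------------------------------
# The split-plot fits


def _aligned_values(
    table: pd.DataFrame, cohort: list[AnimalRecord], measure: MeasureSpec
) -> pd.DataFrame:
    """Per-animal design frame with the measure's analysis-scale value."""
    meta = cohort_frame(cohort)
    meta = meta[meta.present]
    vals = measure_values(table, measure)
    if vals.index.duplicated().any():
        raise DegenerateInputError(
            f"multiple values per animal for measure {measure.measure_id!r}"
        )
    df = meta.set_index("animal_id")
    missing = df.index.difference(vals.index)
    if len(missing):
        raise DegenerateInputError(
            f"no value for present animal(s) {sorted(missing)[:3]} "
            f"in measure {measure.measure_id!r}"
        )
    df = df.assign(value=vals.reindex(df.index))
    for cage, sub in df.groupby("cage_id"):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empty
            raise DegenerateInputError(f"cage {cage} has no animals")
    return df.reset_index()


def _splitplot_blocks(df: pd.DataFrame) -> dict[str, np.ndarray]:
    strain = df.strain.to_numpy()
    time = df.time_group.to_numpy()
    cage = df.cage_id.to_numpy()
    s_col = _sum_contrast(strain, list(STRAINS))
    t_cols = _sum_contrast(time, [t for t in TIME_GROUPS if t in set(time)])
    return {
        "strain": s_col,
        "time": t_cols,
        "time:strain": t_cols * s_col,
        "cage(strain)": _nested_contrast(strain, cage),
    }


def fit_splitplot(
    table: pd.DataFrame,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    alpha: float = 0.05,
) -> SplitPlotResult:
    """Fit the split-plot ANOVA for one non-repeated measure.

    Strain is tested against the cage-within-strain mean square (whole-plot
    stratum); time and time-by-strain against the within-cage residual
    (sub-plot stratum).  Partial eta squared uses each term's own error
    stratum: SS_term / (SS_term + SS_error).
    """
    if measure.repeated:
        raise ValueError("use fit_splitplot_repeated for two-trial measures")
    df = _aligned_values(table, cohort, measure)
    y = df.value.to_numpy(dtype=float)
    n = len(y)
    result = SplitPlotResult(
        measure_id=measure.measure_id,
        terms=[],
        residual_df_subplot=0,
        transform_used=measure.transform,
        n_animals=n,
    )
    total_ss = float(np.sum((y - y.mean()) ** 2))
    blocks = _splitplot_blocks(df)
    ss, rss, df_resid = type3_ss(y, blocks)
    if total_ss == 0:
        result.flagged = True
        result.notes.append("all observations identical; F undefined")
        for name, b in blocks.items():
            result.terms.append(TermResult(name, 0.0, b.shape[1], NAN, NAN, 0, NAN, NAN))
        result.terms.append(TermResult("residual", 0.0, n - 1 - sum(b.shape[1] for b in blocks.values()), NAN, NAN, 0, NAN, NAN))
        result.residual_df_subplot = result.terms[-1].df
        return result
    df_cage = blocks["cage(strain)"].shape[1]
    ms_cage = ss["cage(strain)"] / df_cage
    ms_resid = rss / df_resid if df_resid else NAN
    result.terms = [
        _f_term("strain", ss["strain"], blocks["strain"].shape[1], ms_cage, ss["cage(strain)"], df_cage),
        _f_term("time", ss["time"], blocks["time"].shape[1], ms_resid, rss, df_resid),
        _f_term("time:strain", ss["time:strain"], blocks["time:strain"].shape[1], ms_resid, rss, df_resid),
        _f_term("cage(strain)", ss["cage(strain)"], df_cage, ms_resid, rss, df_resid),
        TermResult("residual", rss, df_resid, ms_resid, NAN, 0, NAN, NAN),
    ]
    result.residual_df_subplot = df_resid
    return result


def fit_splitplot_repeated(
    table: pd.DataFrame,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    alpha: float = 0.05,
    trial_error: str = "cage",
) -> SplitPlotResult:
    """Split-plot ANOVA with the within-animal (trial) stratum.

    The two trials per animal are decomposed into the per-animal mean
    (between-animal stratum, analysed exactly as the non-repeated model)
    and the trial-2 minus trial-1 difference (within-animal stratum, which
    carries trial, trial-by-strain, trial-by-time and the three-way
    trial-by-time-by-strain terms).

    ``trial_error`` selects the error term for the within-animal stratum:
    ``"cage"`` (default) keeps the trial-by-cage-within-strain interaction
    in the model, so trial-level effects are tested against the
    trial-by-animal residual with the same 27 denominator df as the
    sub-plot stratum; ``"pooled"`` pools trial-by-cage into the residual.
    """
    if not measure.repeated:
        raise ValueError("measure is not repeated")
    if trial_error not in ("cage", "pooled"):
        raise ValueError("trial_error must be 'cage' or 'pooled'")
    meta = cohort_frame(cohort)
    meta = meta[meta.present].set_index("animal_id")
    rows = table[table.measure_id == measure.base_id]
    wide = rows.pivot_table(index="animal_id", columns="trial", values="value")
    missing = [
        a
        for a in meta.index
        if a not in wide.index or wide.loc[a].isna().any() or wide.shape[1] != 2
    ]
    if missing or wide.shape[1] != 2:
        raise IncompleteRepeatedError(
            f"missing trial values for {missing[:3]} in {measure.base_id!r}"
        )
    wide = wide.reindex(meta.index)
    means = wide.mean(axis=1).to_numpy()
    diffs = (wide[2.0] - wide[1.0]).to_numpy()
    df = meta.reset_index()
    n = len(df)

    # Between-animal stratum: ANOVA of animal means; SS scale back to the
    # full data (x2 observations per animal).
    blocks = _splitplot_blocks(df)
    ss_b, rss_b, df_resid_b = type3_ss(means, blocks)
    ss_b = {k: 2 * v for k, v in ss_b.items()}
    rss_b *= 2

    # Within-animal stratum: ANOVA of trial differences; the intercept of
    # the difference model is the trial main effect.  SS scale: sum over the
    # two trials of squared deviations from the animal mean = d^2 / 2.
    wblocks = {
        "trial:strain": blocks["strain"],
        "trial:time": blocks["time"],
        "trial:time:strain": blocks["time:strain"],
    }
    if trial_error == "cage":
        wblocks["trial:cage(strain)"] = blocks["cage(strain)"]
    dblocks = {"__intercept__": np.ones((n, 1))} | wblocks
    ss_w, rss_w, df_resid_w = type3_ss(diffs, dblocks, intercept=False)
    ss_w = {k: v / 2 for k, v in ss_w.items()}
    rss_w /= 2

    result = SplitPlotResult(
        measure_id=measure.base_id,
        terms=[],
        residual_df_subplot=df_resid_b,
        transform_used=measure.transform,
        n_animals=n,
    )
    total_ss = float(np.sum((wide.to_numpy() - wide.to_numpy().mean()) ** 2))
    if total_ss == 0:
        result.flagged = True
        result.notes.append("all observations identical; F undefined")

    df_cage = blocks["cage(strain)"].shape[1]
    ms_cage = ss_b["cage(strain)"] / df_cage if df_cage else NAN
    ms_resid_b = rss_b / df_resid_b if df_resid_b else NAN
    ms_resid_w = rss_w / df_resid_w if df_resid_w else NAN
    result.terms = [
        _f_term("strain", ss_b["strain"], 1, ms_cage, ss_b["cage(strain)"], df_cage),
        _f_term("time", ss_b["time"], blocks["time"].shape[1], ms_resid_b, rss_b, df_resid_b),
        _f_term("time:strain", ss_b["time:strain"], blocks["time:strain"].shape[1], ms_resid_b, rss_b, df_resid_b),
        _f_term("cage(strain)", ss_b["cage(strain)"], df_cage, ms_resid_b, rss_b, df_resid_b),
        TermResult("residual(between)", rss_b, df_resid_b, ms_resid_b, NAN, 0, NAN, NAN),
        _f_term("trial", ss_w["__intercept__"], 1, ms_resid_w, rss_w, df_resid_w),
        _f_term("trial:strain", ss_w["trial:strain"], 1, ms_resid_w, rss_w, df_resid_w),
        _f_term("trial:time", ss_w["trial:time"], wblocks["trial:time"].shape[1], ms_resid_w, rss_w, df_resid_w),
        _f_term("trial:time:strain", ss_w["trial:time:strain"], wblocks["trial:time:strain"].shape[1], ms_resid_w, rss_w, df_resid_w),
    ]
    if trial_error == "cage":
        result.terms.append(
            _f_term("trial:cage(strain)", ss_w["trial:cage(strain)"], df_cage, ms_resid_w, rss_w, df_resid_w)
        )
    result.terms.append(
        TermResult("residual(within)", rss_w, df_resid_w, ms_resid_w, NAN, 0, NAN, NAN)
    )
    if result.flagged:
        result.terms = [
            TermResult(t.term, 0.0, t.df, NAN, NAN, t.df_den, NAN, NAN)
            for t in result.terms
        ]
    return result


# ---------------------------------------------------------------------------
# Post hoc machinery


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def posthoc_strain_within_time(
    result: SplitPlotResult,
    table: pd.DataFrame,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    alpha: float = 0.05,
) -> list[PostHocComparison]:
    """Pairwise B6 - D2 contrasts within each testing-time group.

    A strain contrast at a fixed time compares animals in different cages,
    so its standard error mixes the whole-plot and sub-plot variances:
    with t time groups, Var = (1/n1 + 1/n2) * (MS_cage + (t-1) MS_resid) / t.
    The t statistic is referred to the whole-plot (cage) df — the
    conservative classical choice.  p-values are Holm-adjusted across the
    per-measure family.
    """
    df = _aligned_values(table, cohort, measure)
    ms_cage = result.term("cage(strain)").ms
    df_cage = result.term("cage(strain)").df
    resid = result.term("residual") if any(t.term == "residual" for t in result.terms) else result.term("residual(between)")
    ms_resid = resid.ms
    t_levels = len(TIME_GROUPS)
    comparisons: list[tuple[str, float, float, str]] = []
    for tg in TIME_GROUPS:
        g1 = df[(df.time_group == tg) & (df.strain == STRAINS[0])].value
        g2 = df[(df.time_group == tg) & (df.strain == STRAINS[1])].value
        if len(g1) == 0 or len(g2) == 0:
            comparisons.append((f"B6-D2 within {tg}", NAN, NAN, "empty cell"))
            continue
        est = float(g1.mean() - g2.mean())
        se = math.sqrt(
            (1 / len(g1) + 1 / len(g2)) * (ms_cage + (t_levels - 1) * ms_resid) / t_levels
        )
        tstat = est / se
        p = 2 * float(stats.t.sf(abs(tstat), df_cage))
        comparisons.append((f"B6-D2 within {tg}", est, p, ""))
    valid = [c for c in comparisons if not c[3]]
    adjusted = holm_adjust([c[2] for c in valid]) if valid else []
    out: list[PostHocComparison] = []
    it = iter(adjusted)
    for desc, est, p, note in comparisons:
        if note:
            out.append(PostHocComparison(desc, est, p, NAN, False, note))
        else:
            ph = float(next(it))
            out.append(PostHocComparison(desc, est, p, ph, ph < alpha))
    return out


def posthoc_time_within_strain(
    result: SplitPlotResult,
    table: pd.DataFrame,
    cohort: list[AnimalRecord],
    measure: MeasureSpec,
    alpha: float = 0.05,
) -> list[PostHocComparison]:
    """Pairwise time contrasts within each strain (pure sub-plot contrasts).

    Time contrasts within a strain compare animals of the same cages, so
    the cage effect cancels and the within-cage residual mean square with
    its residual df is the appropriate error.
    """
    df = _aligned_values(table, cohort, measure)
    resid = result.term("residual") if any(t.term == "residual" for t in result.terms) else result.term("residual(between)")
    ms_resid, df_resid = resid.ms, resid.df
    comparisons = []
    for s in STRAINS:
        for i, t1 in enumerate(TIME_GROUPS):
            for t2 in TIME_GROUPS[i + 1 :]:
                g1 = df[(df.strain == s) & (df.time_group == t1)].value
                g2 = df[(df.strain == s) & (df.time_group == t2)].value
                if len(g1) == 0 or len(g2) == 0:
                    comparisons.append((f"{t1}-{t2} within {s}", NAN, NAN, "empty cell"))
                    continue
                est = float(g1.mean() - g2.mean())
                se = math.sqrt(ms_resid * (1 / len(g1) + 1 / len(g2)))
                p = 2 * float(stats.t.sf(abs(est / se), df_resid))
                comparisons.append((f"{t1}-{t2} within {s}", est, p, ""))
    valid = [c for c in comparisons if not c[3]]
    adjusted = holm_adjust([c[2] for c in valid]) if valid else []
    out = []
    it = iter(adjusted)
    for desc, est, p, note in comparisons:
        if note:
            out.append(PostHocComparison(desc, est, p, NAN, False, note))
        else:
            ph = float(next(it))
            out.append(PostHocComparison(desc, est, p, ph, ph < alpha))
    return out
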