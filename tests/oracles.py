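"""Independent brute-force oracles used to verify the ANOVA and Wilcoxon
implementations.  Everything here is computed directly from group means or
by exhaustive enumeration, never through the package's fitting code."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def splitplot_ss_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Sums of squares of a balanced split-plot, straight from group means.

    ``df`` needs columns strain, cage_id, time_group, value with one
    observation per cage x time.  Uses the textbook identities: each SS is
    the sum over rows of the squared relevant mean deviation.
    """
    y = df.value.to_numpy(dtype=float)
    grand = y.mean()
    s_mean = df.groupby("strain").value.transform("mean").to_numpy()
    c_mean = df.groupby("cage_id").value.transform("mean").to_numpy()
    t_mean = df.groupby("time_group").value.transform("mean").to_numpy()
    st_mean = df.groupby(["strain", "time_group"]).value.transform("mean").to_numpy()
    return {
        "strain": float(((s_mean - grand) ** 2).sum()),
        "cage(strain)": float(((c_mean - s_mean) ** 2).sum()),
        "time": float(((t_mean - grand) ** 2).sum()),
        "time:strain": float(((st_mean - s_mean - t_mean + grand) ** 2).sum()),
        "residual": float(((y - c_mean - st_mean + s_mean) ** 2).sum()),
    }


def twoway_anova_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Balanced two-way (strain x replicate) SS partition from cell means."""
    y = df.value.to_numpy(dtype=float)
    grand = y.mean()
    a = df.groupby("strain").value.transform("mean").to_numpy()
    b = df.groupby("replicate").value.transform("mean").to_numpy()
    ab = df.groupby(["strain", "replicate"]).value.transform("mean").to_numpy()
    return {
        "strain": float(((a - grand) ** 2).sum()),
        "replicate": float(((b - grand) ** 2).sum()),
        "strain:replicate": float(((ab - a - b + grand) ** 2).sum()),
        "residual": float(((y - ab) ** 2).sum()),
    }


def signed_rank_p_bruteforce(d: np.ndarray) -> float:
    """One-tailed P(W <= w_obs) by enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def holm_oracle(p: list[float]) -> list[float]:
    """Step-down Holm applied literally to a list of p-values."""
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()
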