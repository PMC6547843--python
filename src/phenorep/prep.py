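"""Variable transformations and residual-normality diagnostics.

Behavioural measures (times, counts, proportions) rarely satisfy the
normality and homoscedasticity assumptions of a parametric ANOVA on their
raw scale.  The standard remedies in this field are the square-root
transform for counts, the log or inverse transform for latencies, and the
angular (arcsine-square-root) transform for proportions.  This module
applies those transforms, their inverses, and a Shapiro-Wilk check on model
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

TRANSFORM_KINDS = ("none", "sqrt", "log", "inverse", "angular")


class TransformDomainError(ValueError):
    """A value falls outside the transform's domain (reports the index)."""


class DiagnosticError(ValueError):
    """Degenerate input for a normality diagnostic."""


@dataclass(frozen=True)
class TransformSpec:
    """A variance-stabilising transform.

    Parameters
    ----------
    kind
        One of ``none``, ``sqrt``, ``log``, ``inverse``, ``angular``.
    offset
        Constant added before ``sqrt``/``log``/``inverse`` so that
        zero-valued observations (e.g. zero entries into the light
        compartment) stay inside the domain.  Ignored for ``none`` and
        ``angular``.
    """

    kind: str = "none"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk test result for a residual vector."""

    statistic: float
    p_value: float
    n: int


def _check_domain(x: np.ndarray, ok: np.ndarray, spec: TransformSpec) -> None:
    if not np.all(ok):
        idx = int(np.flatnonzero(~ok)[0])
        raise TransformDomainError(
            f"value {x[idx]!r} at index {idx} outside domain of "
            f"{spec.kind!r} transform (offset={spec.offset})"
        )


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Apply ``spec`` elementwise; order and length are preserved.

    ``sqrt``/``log``/``inverse`` act on ``x + offset``; ``angular`` is
    ``arcsin(sqrt(x))`` and requires values in [0, 1].
    """
    x = np.asarray(values, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(x))[0])
        raise TransformDomainError(f"non-finite value at index {idx}")
    if spec.kind == "none":
        return x.copy()
    if spec.kind == "sqrt":
        shifted = x + spec.offset
        _check_domain(x, shifted >= 0, spec)
        return np.sqrt(shifted)
    if spec.kind == "log":
        shifted = x + spec.offset
        _check_domain(x, shifted > 0, spec)
        return np.log(shifted)
    if spec.kind == "inverse":
        shifted = x + spec.offset
        _check_domain(x, shifted != 0, spec)
        return 1.0 / shifted
    # angular
    _check_domain(x, (x >= 0) & (x <= 1), spec)
    return np.arcsin(np.sqrt(x))


def inverse_transform(values, spec: TransformSpec) -> np.ndarray:
    """Map analysis-scale values back to the raw scale (inverse of
    :func:`apply_transform`)."""
    y = np.asarray(values, dtype=float)
    if spec.kind == "none":
        return y.copy()
    if spec.kind == "sqrt":
        return y**2 - spec.offset
    if spec.kind == "log":
        return np.exp(y) - spec.offset
    if spec.kind == "inverse":
        return 1.0 / y - spec.offset
    return np.sin(y) ** 2


def check_residual_normality(residuals) -> NormalityReport:
    """Shapiro-Wilk W and p for a residual vector.

    Raises :class:`DiagnosticError` for n < 3 or a constant vector, where
    W is undefined.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise DiagnosticError(f"need at least 3 residuals, got {r.size}")
    if np.ptp(r) == 0:
        raise DiagnosticError("residuals have zero variance")
    w, p = stats.shapiro(r)
    return NormalityReport(statistic=float(w), p_value=float(p), n=int(r.size))
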