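"""Means with 95 % confidence intervals and quadrature error propagation.

Every quantity the budget pipeline reports is an :class:`UncertainValue`:
a mean ``M`` with a 95 % CI half-width ``E`` in the same units.  CIs on
sample means are Student-t based (regime sample sizes are small, n ~ 3-25).
Propagation through sums, differences and quotients follows the quadrature
rules

    (M1 ± E1) + (M2 ± E2) = (M1 + M2) ± sqrt(E1^2 + E2^2)
    (M1 ± E1) - (M2 ± E2) = (M1 - M2) ± sqrt(E1^2 + E2^2)
    (M1 ± E1) / (M2 ± E2) = (M1/M2) ± (M1/M2) sqrt((E1/M2)^2 + (E2/M2)^2)

The quotient rule above normalises both error terms by the denominator
mean M2.  Standard relative-error propagation would use E1/M1 in the first
term; both forms are supported (``quotient_form``), the M2-normalised form
is the default, and a divergence of more than 1 % between the two is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "UncertainValue",
    "mean_with_ci",
    "propagate",
    "scale",
    "round_sig",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertainValue:
    """A mean with a symmetric 95 % confidence half-width.

    Parameters
    ----------
    m : float
        Mean value, any units.
    e : float
        95 % CI half-width, same units.  ``nan`` marks an undefined CI
        (e.g. a single-sample mean).
    n : int, optional
        Number of samples behind the mean, when it came from data.
    """

    m: float
    e: float
    n: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.e) and self.e < 0:
            raise ValueError(f"CI half-width must be >= 0, got {self.e}")

    @property
    def ci_defined(self) -> bool:
        return bool(np.isfinite(self.e))

    def __format__(self, spec: str) -> str:
        spec = spec or ".3g"
        return f"{self.m:{spec}} +/- {self.e:{spec}}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return format(self)


def mean_with_ci(values, *, method: str = "t") -> UncertainValue:
    """Sample mean with a 95 % CI half-width.

    ``method='t'`` (default) uses t(0.975, n-1) x s/sqrt(n); ``'normal'``
    uses 1.96 x s/sqrt(n).  A single value yields a flagged (nan) CI.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("mean_with_ci requires at least one value")
    if x.size == 1:
        return UncertainValue(float(x[0]), float("nan"), 1)
    se = float(np.std(x, ddof=1)) / math.sqrt(x.size)
    if method == "t":
        crit = float(_st.t.ppf(0.975, x.size - 1))
    elif method == "normal":
        crit = 1.959963984540054
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return UncertainValue(float(np.mean(x)), crit * se, int(x.size))


def _e(v: UncertainValue) -> float:
    # treat an undefined CI as zero-width for propagation, the flag is on v
    return v.e if np.isfinite(v.e) else 0.0


def propagate(
    op: str,
    a: UncertainValue,
    b: UncertainValue,
    *,
    quotient_form: str = "as_reported",
) -> UncertainValue:
    """Propagate 95 % CIs through ``sum``, ``difference`` or ``quotient``.

    ``quotient_form`` selects how the numerator error enters the quotient
    rule: ``"as_reported"`` divides both E1 and E2 by the denominator mean
    M2; ``"standard"`` uses the usual relative errors (E1/M1, E2/M2).
    """
    e1, e2 = _e(a), _e(b)
    if op in ("sum", "add", "+"):
        return UncertainValue(a.m + b.m, math.hypot(e1, e2))
    if op in ("difference", "subtract", "-"):
        return UncertainValue(a.m - b.m, math.hypot(e1, e2))
    if op in ("quotient", "divide", "/"):
        if b.m == 0:
            raise ZeroDivisionError("quotient propagation with zero denominator mean")
        q = a.m / b.m
        err_rep = abs(q) * math.hypot(e1 / b.m, e2 / b.m)
        if a.m != 0:
            err_std = abs(q) * math.hypot(e1 / a.m, e2 / b.m)
        else:
            err_std = abs(e1 / b.m)
        if err_rep > 0 and abs(err_std - err_rep) > 0.01 * err_rep:
            log.debug(
                "quotient CI forms differ by >1%%: reported=%.4g standard=%.4g",
                err_rep,
                err_std,
            )
        err = err_rep if quotient_form == "as_reported" else err_std
        return UncertainValue(q, abs(err))
    raise ValueError(f"unknown propagation op {op!r}")


def scale(v: UncertainValue, k: float) -> UncertainValue:
    """Multiply an uncertain value by an exact scalar (CI scales with |k|)."""
    return UncertainValue(v.m * k, abs(_e(v) * k) if np.isfinite(v.e) else v.e, v.n)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
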