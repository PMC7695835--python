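"""Substrate-depletion pharmacokinetics.

First-order half-life from percent-remaining series (log-linear
regression of ln(%) on time) and microsomal intrinsic clearance
CLint = ln(2) / (t1/2 * protein concentration), in ul/min/mg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["DepletionSeries", "DepletionFit", "halflife_from_depletion", "intrinsic_clearance"]


@dataclass
class DepletionSeries:
    """Percent of compound remaining over an incubation.

    times in minutes (ascending, >= 0); pct_remaining as percent of the
    t=0 level (values slightly above 100 tolerated as noise); ``matrix``
    labels the incubation (microsome/plasma/buffer); protein_conc in
    mg protein per ul, used only for microsomal clearance.
    """

    times: np.ndarray
    pct_remaining: np.ndarray
    matrix: str = "microsome"
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pct_remaining = np.asarray(self.pct_remaining, dtype=float)
        if self.times.shape != self.pct_remaining.shape or self.times.ndim != 1:
            raise ValueError("times and pct_remaining must be 1-D and equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-negative and ascending")
        if self.times.size and np.isclose(self.times[0], 0.0):
            p0 = self.pct_remaining[0]
            if not (90.0 <= p0 <= 110.0):
                warnings.warn(
                    f"t=0 percent remaining {p0:.1f} outside the [90, 110] sanity band",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class DepletionFit:
    """First-order depletion fit: rate k (min^-1, <= 0 for depletion) and t1/2."""

    k: float
    t_half: float
    r2: float
    stable: bool
    n_used: int
    flags: tuple = ()


def halflife_from_depletion(series: DepletionSeries) -> DepletionFit:
    """First-order half-life from a percent-remaining series.

    k is the slope of ln(percent remaining) vs time (expected <= 0);
    t1/2 = -ln(2)/k.  Non-positive percentages are excluded with a
    warning (their logarithm is undefined).  A non-negative slope means
    no measurable depletion: t1/2 is reported as +inf with the ``stable``
    flag set.
    """
    t = series.times
    p = series.pct_remaining
    keep = p > 0
    flags = []
    if not np.all(keep):
        warnings.warn(
            f"excluding {int(np.sum(~keep))} point(s) with percent remaining <= 0",
            stacklevel=2,
        )
        flags.append("nonpositive-points-excluded")
        t, p = t[keep], p[keep]
    if len(t) < 2:
        raise ValueError("need >= 2 usable time points")
    if len(t) == 2:
        k = (np.log(p[1]) - np.log(p[0])) / (t[1] - t[0])
        r2 = 1.0
    else:
        lin = stats.linregress(t, np.log(p))
        k, r2 = float(lin.slope), float(lin.rvalue**2)
    if k >= 0:
        flags.append("stable: no measurable depletion")
        return DepletionFit(k=float(k), t_half=np.inf, r2=r2, stable=True, n_used=len(t), flags=tuple(flags))
    t_half = -np.log(2.0) / k
    return DepletionFit(k=float(k), t_half=float(t_half), r2=r2, stable=False, n_used=len(t), flags=tuple(flags))


def intrinsic_clearance(t_half: float, protein_conc: float) -> float:
    """Microsomal intrinsic clearance CLint = ln(2)/(t1/2 * protein) in ul/min/mg.

    t_half in minutes, protein_conc in mg protein per ul.  An infinite
    half-life (stable compound) gives CLint = 0.
    """
    if not protein_conc > 0:
        raise ValueError(f"protein_conc must be positive, got {protein_conc!r}")
    if np.isinf(t_half):
        return 0.0
    if not t_half > 0:
        raise ValueError(f"t_half must be positive, got {t_half!r}")
    return float(np.log(2.0) / (t_half * protein_conc))
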