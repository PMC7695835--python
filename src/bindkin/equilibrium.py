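"""Equilibrium pharmacology: dose-response fitting, Schild and affinity analysis.

Covers the standard endpoint analyses of a functional antagonist study:

* normalisation of raw plate signals to reference wells,
* 3-parameter logistic (fixed unit Hill slope) concentration-response
  fits, with an optional free-slope 4-parameter variant,
* dose ratios and Schild regression (pA2; pKB with the slope constrained
  to unity),
* saturation binding (KD, Bmax),
* Cheng-Prusoff conversion of competition IC50 to Ki and a one-site
  competition fit built on it.

Concentrations are molar; potencies are reported as negative base-10
logarithms (pIC50/pEC50/pKi/pKB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "SchildResult",
    "SaturationFit",
    "normalize_response",
    "fit_logistic3",
    "fit_logistic4",
    "dose_ratio",
    "schild_regression",
    "fit_saturation",
    "cheng_prusoff",
    "one_site_competition_fit",
    "welch_ttest",
]


@dataclass
class DoseResponseCurve:
    """A fitted concentration-response curve.

    ``direction`` is "stimulation" (response rises with concentration) or
    "inhibition" (falls).  ``p50`` is pEC50 for stimulation, pIC50 for
    inhibition.  ``span`` = |top - bottom|.
    """

    conc: np.ndarray
    response: np.ndarray
    top: float
    bottom: float
    logEC50: float
    direction: str
    hill: float = 1.0
    se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def p50(self) -> float:
        return -self.logEC50

    @property
    def EC50(self) -> float:
        return 10.0 ** self.logEC50

    @property
    def span(self) -> float:
        return abs(self.top - self.bottom)


@dataclass(frozen=True)
class SchildResult:
    """Schild regression of log10(DR - 1) on log10 antagonist concentration."""

    antagonist_concs: tuple
    dose_ratios: tuple
    slope: float
    slope_se: float
    pA2: float
    pKB: float
    excluded: tuple = ()


@dataclass(frozen=True)
class SaturationFit:
    """One-site saturation binding fit B = Bmax*[L]/(KD+[L])."""

    KD: float
    Bmax: float
    KD_se: float
    Bmax_se: float
    flags: tuple = ()


def normalize_response(raw, reference_max: float, reference_min: float, mode: str = "inhibition"):
    """Map raw signal linearly onto a percent-of-reference scale.

    reference_max maps to 100, reference_min to 0.  ``mode`` records the
    assay orientation (e.g. percent forskolin inhibition vs stimulation);
    both modes use the same linear map — the references themselves carry
    the orientation.  Values outside [0, 100] pass through unclamped
    (responses below the zero reference are reported as negative
    percentages).
    """
    if mode not in ("inhibition", "stimulation"):
        raise ValueError(f"mode must be 'inhibition' or 'stimulation', got {mode!r}")
    if reference_max == reference_min:
        raise ValueError("degenerate references: reference_max == reference_min")
    raw = np.asarray(raw, dtype=float)
    out = 100.0 * (raw - reference_min) / (reference_max - reference_min)
    return float(out) if out.ndim == 0 else out


def _logistic(logx, top, bottom, logec50, s):
    # Y = bottom + (top-bottom)/(1 + 10^((logEC50 - logX)*s))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logx) * s))


def _runs_test_p(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test on residual signs (normal approximation)."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _fit_logistic(
    conc,
    response,
    direction: str | None,
    free_slope: bool,
) -> DoseResponseCurve:
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape or conc.ndim != 1:
        raise ValueError("conc and response must be 1-D arrays of equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (molar)")
    if len(np.unique(conc)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    logx = np.log10(conc)

    # infer direction from the data if not given
    order = np.argsort(logx)
    lo_resp = float(np.mean(response[order][: max(len(conc) // 4, 1)]))
    hi_resp = float(np.mean(response[order][-max(len(conc) // 4, 1):]))
    if direction is None:
        direction = "stimulation" if hi_resp >= lo_resp else "inhibition"
    s = 1.0 if direction == "stimulation" else -1.0

    flags = []
    top0 = float(np.max(response))
    bot0 = float(np.min(response))
    mid0 = float(np.median(logx))
    if free_slope:
        p0 = [top0, bot0, mid0, s]
        lb = [-np.inf, -np.inf, logx.min() - 6, -10 if s < 0 else 0.01]
        ub = [np.inf, np.inf, logx.max() + 6, -0.01 if s < 0 else 10]

        def model(lx, top, bottom, logec50, slope):
            return _logistic(lx, top, bottom, logec50, slope)
    else:
        p0 = [top0, bot0, mid0]
        lb = [-np.inf, -np.inf, logx.min() - 6]
        ub = [np.inf, np.inf, logx.max() + 6]

        def model(lx, top, bottom, logec50):
            return _logistic(lx, top, bottom, logec50, s)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(model, logx, response, p0=p0, bounds=(lb, ub), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    top, bottom, logec50 = popt[0], popt[1], popt[2]
    hill = abs(popt[3]) if free_slope else 1.0

    span = abs(top - bottom)
    resid = response - model(logx, *popt)
    noise = np.sqrt(np.mean(resid**2))
    # flat curve: fitted span indistinguishable from noise
    if span < 3.0 * max(noise, 1e-12 * max(abs(top), 1.0)):
        flags.append("no-inhibition" if direction == "inhibition" else "no-response")
    conc_span = logx.max() - logx.min()
    if conc_span < 1.0:
        flags.append("wide-CI: concentration range spans < 1 log unit")
    if not (logx.min() <= logec50 <= logx.max()):
        flags.append("EC50 outside tested concentration range")
    if np.isfinite(perr[2]) and perr[2] > 1.0:
        flags.append("wide-CI: logEC50 standard error > 1 log unit")
    if (
        len(resid) >= 8
        and noise > 1e-8 * max(span, abs(top), 1e-300)
        and _runs_test_p(resid) < 0.025
    ):
        flags.append("lack-of-fit: systematic residual runs")

    se = {"top": float(perr[0]), "bottom": float(perr[1]), "logEC50": float(perr[2])}
    if free_slope:
        se["hill"] = float(perr[3])
    return DoseResponseCurve(
        conc=conc,
        response=response,
        top=float(top),
        bottom=float(bottom),
        logEC50=float(logec50),
        direction=direction,
        hill=float(hill),
        se=se,
        flags=flags,
    )


def fit_logistic3(conc, response, direction: str | None = None) -> DoseResponseCurve:
    """Fit the 3-parameter logistic (unit Hill slope) to a dose-response table.

    Y = bottom + (top - bottom) / (1 + 10^((logEC50 - logX) * s)) with the
    slope s fixed at +1 (stimulation) or -1 (inhibition).  ``direction``
    is inferred from the data when omitted.  Returns fitted plateaus,
    logEC50 (p50 = -logEC50), standard errors and quality flags.
    """
    return _fit_logistic(conc, response, direction, free_slope=False)


def fit_logistic4(conc, response, direction: str | None = None) -> DoseResponseCurve:
    """4-parameter logistic with free Hill slope (diagnostic alternative)."""
    return _fit_logistic(conc, response, direction, free_slope=True)


def dose_ratio(p50_control: float, p50_with_antagonist: float) -> tuple[float, bool]:
    """Fold rightward shift of the agonist curve caused by an antagonist.

    DR = 10^(p50_control - p50_antagonist).  Returns (DR, shifted) where
    ``shifted`` is False when DR <= 1 (no rightward shift; unusable for
    Schild analysis).
    """
    if not (np.isfinite(p50_control) and np.isfinite(p50_with_antagonist)):
        raise ValueError("p50 values must be finite")
    dr = 10.0 ** (p50_control - p50_with_antagonist)
    return float(dr), bool(dr > 1.0)


def schild_regression(antagonist_concs, dose_ratios) -> SchildResult:
    """Schild analysis: regress log10(DR - 1) on log10[B].

    The x-intercept gives pA2; refitting with the slope constrained to
    unity gives the affinity estimate pKB (identical to pA2 when the
    unconstrained slope is exactly 1).  Points with DR <= 1 are excluded
    with a warning; at least two usable points are required.
    """
    B = np.asarray(antagonist_concs, dtype=float)
    DR = np.asarray(dose_ratios, dtype=float)
    if B.shape != DR.shape or B.ndim != 1:
        raise ValueError("antagonist_concs and dose_ratios must be 1-D and equal length")
    if np.any(B <= 0):
        raise ValueError("antagonist concentrations must be positive (molar)")
    usable = DR > 1.0
    excluded = tuple(float(b) for b in B[~usable])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} point(s) with dose ratio <= 1", stacklevel=2
        )
    B, DR = B[usable], DR[usable]
    if len(B) < 2:
        raise ValueError("Schild regression needs >= 2 points with DR > 1")
    x = np.log10(B)
    y = np.log10(DR - 1.0)
    if len(B) == 2 and np.isclose(x[0], x[1]):
        raise ValueError("antagonist concentrations must differ")
    lin = stats.linregress(x, y)
    slope, intercept = float(lin.slope), float(lin.intercept)
    pA2 = intercept / slope  # -x-intercept: slope*x0 + intercept = 0 -> pA2 = -x0
    # slope-unity refit: log(DR-1) = log[B] + pKB
    pKB = float(np.mean(y - x))
    return SchildResult(
        antagonist_concs=tuple(float(b) for b in B),
        dose_ratios=tuple(float(d) for d in DR),
        slope=slope,
        slope_se=float(lin.stderr) if len(B) > 2 else np.nan,
        pA2=float(pA2),
        pKB=pKB,
        excluded=excluded,
    )


def fit_saturation(conc, specific_signal) -> SaturationFit:
    """One-site saturation binding: B = Bmax*[L]/(KD + [L]).

    Requires >= 5 concentrations; flags the fit when the top plateau is
    unresolved (tested concentrations do not reach KD).
    """
    L = np.asarray(conc, dtype=float)
    B = np.asarray(specific_signal, dtype=float)
    if L.shape != B.shape or L.ndim != 1:
        raise ValueError("conc and signal must be 1-D and equal length")
    if np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(L)) < 5:
        raise ValueError("need >= 5 distinct concentrations")

    Bmax0 = float(np.max(B)) or 1.0
    KD0 = float(np.median(L[L > 0]))

    def model(l, bmax, kd):
        return bmax * l / (kd + l)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            model, L, B, p0=[Bmax0, KD0], bounds=([0, 0], [np.inf, np.inf]), maxfev=20000
        )
    Bmax, KD = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    flags = []
    if KD > float(np.max(L)):
        flags.append("top unresolved: KD above highest tested concentration")
    elif np.isfinite(perr[1]) and perr[1] > KD:
        flags.append("top unresolved: KD standard error exceeds estimate")
    return SaturationFit(
        KD=KD, Bmax=Bmax, KD_se=float(perr[1]), Bmax_se=float(perr[0]), flags=tuple(flags)
    )


def cheng_prusoff(IC50: float, L: float, KD: float) -> tuple[float, float]:
    """Convert a competition IC50 into an affinity: Ki = IC50/(1 + [L]/KD).

    [L] is the tracer concentration and KD its equilibrium dissociation
    constant, both molar.  Returns (Ki, pKi).
    """
    for name, v in (("IC50", IC50), ("L", L), ("KD", KD)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    Ki = IC50 / (1.0 + L / KD)
    return float(Ki), float(-np.log10(Ki))


def one_site_competition_fit(
    conc,
    bound_signal,
    L: float,
    KD: float,
) -> tuple[float, DoseResponseCurve]:
    """One-site competition: inhibition curve with unit Hill slope, then Cheng-Prusoff.

    Fits the bound-tracer signal vs competitor concentration with the
    fixed-slope logistic, converts the fitted IC50 to Ki given the tracer
    concentration and KD, and returns (pKi, fitted curve).  A flat curve
    is flagged 'no-inhibition' (pKi is then meaningless); systematic
    residual runs (e.g. data with Hill slope far from 1) raise a
    lack-of-fit flag on the curve.
    """
    curve = fit_logistic3(conc, bound_signal, direction="inhibition")
    if "no-inhibition" in curve.flags:
        return float("nan"), curve
    IC50 = curve.EC50
    _, pKi = cheng_prusoff(IC50, L, KD)
    return pKi, curve


def welch_ttest(mean1, se1, n1, mean2, se2, n2) -> tuple[float, float]:
    """Welch t-test from summary statistics (for fit-parameter contrasts).

    Inputs are means, standard errors (not SDs) and group sizes; returns
    (t, two-sided p) with Welch-Satterthwaite degrees of freedom.
    """
    v1, v2 = se1**2, se2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p
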