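"""Nonlinear least-squares fitting of kinetic binding traces.

Two-step workflow mirroring standard competition-kinetics practice:

1. :func:`fit_tracer_kinetics` determines the tracer rate constants
   (k1, k2) and the maximal signal N from tracer-only association traces
   at several tracer concentrations (global fit of the mono-exponential
   association model, shared parameters across traces).
2. With (k1, k2) fixed, :func:`fit_competition_full` fits the full
   two-ligand competition model (free k3, k4, N shared across competitor
   concentrations) and :func:`fit_competition_rapid` fits the
   rapid-competitor-dissociation model (free Ki, N).  The two fits are
   compared with an extra-sum-of-squares partial F-test
   (:func:`compare_models`); the extra parameters of the full model are
   retained only if they significantly improve the fit.

Rate and affinity parameters are optimised in log10 space so positivity
holds by construction; each fit runs from several log-spaced starts and
keeps the lowest-SSR solution.  Standard errors come from the Gauss-Newton
approximation J'J at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .models import (
    KineticTrace,
    TracerKinetics,
    CompetitorKinetics,
    RapidCompetitor,
    motulsky_mahan_occupancy,
    rapid_competition_occupancy,
)

__all__ = [
    "FitResult",
    "CompetitionFit",
    "ModelComparison",
    "InsufficientDesignError",
    "fit_tracer_kinetics",
    "fit_competition_full",
    "fit_competition_rapid",
    "compare_models",
    "fit_competition_auto",
]

MONO_EXPONENTIAL = "mono_exponential"
MOTULSKY_MAHAN = "motulsky_mahan"
RAPID_DISSOCIATION = "rapid_dissociation"

# ambiguity heuristics (the fit is reported, but flagged)
_SE_RATIO_AMBIGUOUS = 10.0   # SE > 10x estimate
_BOUND_REL_TOL = 0.01        # estimate within 1% of a box bound
_LOG_BOUNDS = (-12.0, 12.0)  # log10 box for all rate/affinity parameters


class InsufficientDesignError(ValueError):
    """The experimental design cannot identify the requested parameters."""


@dataclass
class FitResult:
    """Outcome of one least-squares fit.

    params/se are keyed by parameter name on the natural (linear) scale.
    ``dof`` is n_points - n_free_params; ``converged`` is the optimiser's
    success flag; ``ambiguous`` marks poorly identified parameters.
    """

    model: str
    params: dict
    se: dict
    ssr: float
    dof: int
    n_points: int
    converged: bool
    ambiguous: bool = False
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "se": dict(self.se),
            "ssr": self.ssr,
            "dof": self.dof,
            "n_points": self.n_points,
            "converged": self.converged,
            "ambiguous": self.ambiguous,
            "flags": list(self.flags),
        }


@dataclass
class CompetitionFit:
    """Competition-fit summary: the FitResult plus derived pharmacology."""

    fit: FitResult
    Ki: float
    pKi: float
    k3: float | None = None
    k4: float | None = None
    residence_time: float | None = None

    def to_dict(self) -> dict:
        d = self.fit.to_dict()
        d.update(
            Ki=self.Ki,
            pKi=self.pKi,
            k3=self.k3,
            k4=self.k4,
            residence_time=self.residence_time,
        )
        return d


@dataclass(frozen=True)
class ModelComparison:
    """Partial F-test between a simpler and a more complex nested fit."""

    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    selected: str


def _multistart_lsq(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds=_LOG_BOUNDS,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Run least_squares from several starts; return (x, jac, converged) of best SSR."""
    best = None
    lo, hi = bounds
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-6, hi - 1e-6)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    sol = best[1]
    return sol.x, sol.jac, bool(sol.success)


def _se_from_jacobian(jac: np.ndarray, ssr: float, dof: int) -> np.ndarray:
    """Asymptotic standard errors from the Gauss-Newton Hessian J'J."""
    if dof <= 0:
        return np.full(jac.shape[1], np.nan)
    s2 = ssr / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        var = np.diag(cov)
        return np.sqrt(np.where(var > 0, var, np.nan))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def _log_se_to_linear(value: float, se_log: float) -> float:
    """SE of 10**x from SE of x (delta method)."""
    return value * np.log(10.0) * se_log if np.isfinite(se_log) else np.nan


def _ambiguity_flags(x: np.ndarray, se_log: np.ndarray, names: Sequence[str], converged: bool) -> list:
    flags = []
    lo, hi = _LOG_BOUNDS
    span = hi - lo
    for xi, sei, name in zip(x, se_log, names):
        if not np.isfinite(sei) or sei > _SE_RATIO_AMBIGUOUS * max(abs(xi), 1.0):
            flags.append(f"{name}: standard error much larger than estimate")
        if min(xi - lo, hi - xi) < _BOUND_REL_TOL * span:
            flags.append(f"{name}: estimate at parameter bound")
    if not converged:
        flags.append("optimiser did not converge")
    return flags


def _check_traces(traces: Sequence[KineticTrace], min_points: int = 5) -> None:
    if not traces:
        raise InsufficientDesignError("no traces supplied")
    for tr in traces:
        if len(tr.times) < min_points:
            raise InsufficientDesignError(
                f"each trace needs >= {min_points} time points, got {len(tr.times)}"
            )


def fit_tracer_kinetics(
    traces: Sequence[KineticTrace],
    n_starts: int = 5,
) -> tuple[TracerKinetics, FitResult, dict]:
    """Globally fit tracer association traces (competitor-free) for k1, k2, N.

    Requires traces at >= 3 distinct tracer concentrations, each with >= 5
    time points.  The model per trace is mono-exponential association

        B(t) = N [L] k1 / ([L]k1 + k2) * (1 - exp(-([L]k1 + k2) t))

    with k1, k2, N shared.  Also returns, in the info dict, the per-trace
    observed rates k_obs and the classical linear-regression alternative
    (k_obs vs [L]: slope k1, intercept k2).
    """
    _check_traces(traces)
    if any(tr.I != 0 for tr in traces):
        raise InsufficientDesignError("tracer-only fit requires competitor-free traces (I == 0)")
    Ls = sorted({tr.L for tr in traces})
    if len(Ls) < 3:
        raise InsufficientDesignError(
            f"need traces at >= 3 distinct tracer concentrations, got {len(Ls)}"
        )

    t_all = [tr.times for tr in traces]
    y_all = [tr.signal for tr in traces]
    n_points = int(sum(len(t) for t in t_all))
    sig_scale = max(float(np.max(np.abs(np.concatenate(y_all)))), 1e-12)
    Lmid = float(np.median(Ls))

    def residual(x: np.ndarray) -> np.ndarray:
        k1, k2, N = 10.0 ** x
        res = []
        for tr, t, y in zip(traces, t_all, y_all):
            kobs = tr.L * k1 + k2
            pred = N * tr.L * k1 / kobs * (1.0 - np.exp(-kobs * t))
            res.append(pred - y)
        return np.concatenate(res)

    # log-spaced starts around a crude guess: k2 ~ 1/t_scale, k1 ~ k2/Lmid
    t_scale = float(np.median(np.concatenate(t_all))) or 1.0
    base = np.array([np.log10(1.0 / (t_scale * Lmid)), np.log10(1.0 / t_scale), np.log10(sig_scale)])
    rng = np.random.default_rng(0)
    starts = [base] + [base + rng.uniform(-1.5, 1.5, 3) for _ in range(n_starts - 1)]

    x, jac, converged = _multistart_lsq(residual, starts)
    k1, k2, N = 10.0 ** x
    ssr = float(np.sum(residual(x) ** 2))
    dof = n_points - 3
    se_log = _se_from_jacobian(jac, ssr, dof)
    names = ["k1", "k2", "N"]
    flags = _ambiguity_flags(x, se_log, names, converged)
    result = FitResult(
        model=MONO_EXPONENTIAL,
        params={"k1": k1, "k2": k2, "N": N, "KD": k2 / k1},
        se={n: _log_se_to_linear(v, s) for n, v, s in zip(names, (k1, k2, N), se_log)},
        ssr=ssr,
        dof=dof,
        n_points=n_points,
        converged=converged,
        ambiguous=bool(flags),
        flags=flags,
    )

    # per-trace kobs and the linear alternative
    kobs_per_trace = {}
    for tr in traces:
        def res1(x1, tr=tr):
            kobs, Nloc = 10.0 ** x1
            plateau = Nloc
            return plateau * (1.0 - np.exp(-kobs * tr.times)) - tr.signal

        x1, _, _ = _multistart_lsq(
            res1, [np.array([np.log10(1.0 / t_scale), np.log10(sig_scale)])]
        )
        kobs_per_trace[tr.L] = 10.0 ** x1[0]
    Lv = np.array(sorted(kobs_per_trace))
    kv = np.array([kobs_per_trace[L] for L in Lv])
    lin = stats.linregress(Lv, kv)
    info = {
        "kobs_per_trace": kobs_per_trace,
        "kobs_regression": {
            "k1": float(lin.slope),
            "k2": float(lin.intercept),
            "r2": float(lin.rvalue**2),
        },
    }
    return TracerKinetics(k1=k1, k2=k2, N=N), result, info


def _check_competition_design(traces: Sequence[KineticTrace]) -> None:
    _check_traces(traces)
    Is = sorted({tr.I for tr in traces})
    nonzero = [i for i in Is if i > 0]
    if len(nonzero) < 1:
        raise InsufficientDesignError("competition fit requires traces with competitor present")
    if len(nonzero) < 2:
        raise InsufficientDesignError(
            "competition fit requires >= 2 non-zero competitor concentrations"
        )


def _competition_starts(traces, tracer, rng_seed=0, n_starts=5, n_params=3):
    sig_scale = max(float(np.max(np.abs(np.concatenate([tr.signal for tr in traces])))), 1e-12)
    Imid = float(np.median([tr.I for tr in traces if tr.I > 0]))
    t_scale = float(np.median(np.concatenate([tr.times for tr in traces]))) or 1.0
    if n_params == 3:  # log10(k3), log10(k4), log10(N)
        base = np.array(
            [np.log10(1.0 / (t_scale * Imid)), np.log10(1.0 / t_scale), np.log10(sig_scale)]
        )
    else:  # log10(Ki), log10(N)
        base = np.array([np.log10(Imid), np.log10(sig_scale)])
    rng = np.random.default_rng(rng_seed)
    return [base] + [base + rng.uniform(-1.5, 1.5, n_params) for _ in range(n_starts - 1)]


def fit_competition_full(
    traces: Sequence[KineticTrace],
    tracer: TracerKinetics,
    n_starts: int = 5,
) -> CompetitionFit:
    """Fit the full two-ligand competition model for k3, k4 (and N).

    Tracer constants k1, k2 are held fixed from the tracer-only fit; k3,
    k4 and N are shared across all competitor concentrations.  Derived
    quantities: Ki = k4/k3, pKi, residence time 1/k4.  Poorly identified
    fits (typically very fast competitor dissociation) are flagged
    ambiguous rather than rejected.
    """
    _check_competition_design(traces)
    names = ["k3", "k4", "N"]

    def residual(x: np.ndarray) -> np.ndarray:
        k3, k4, N = 10.0 ** x
        tr_k = TracerKinetics(k1=tracer.k1, k2=tracer.k2, N=N)
        comp = CompetitorKinetics(k3=k3, k4=k4)
        return np.concatenate(
            [
                motulsky_mahan_occupancy(tr.times, tr_k, comp, tr.L, tr.I) - tr.signal
                for tr in traces
            ]
        )

    starts = _competition_starts(traces, tracer, n_starts=n_starts, n_params=3)
    x, jac, converged = _multistart_lsq(residual, starts)
    k3, k4, N = 10.0 ** x
    ssr = float(np.sum(residual(x) ** 2))
    n_points = int(sum(len(tr.times) for tr in traces))
    dof = n_points - 3
    se_log = _se_from_jacobian(jac, ssr, dof)
    flags = _ambiguity_flags(x, se_log, names, converged)
    if k4 > 1.0:
        flags.append("k4 > 1 min^-1: dissociation too fast to resolve reliably")
    fit = FitResult(
        model=MOTULSKY_MAHAN,
        params={"k3": k3, "k4": k4, "N": N},
        se={n: _log_se_to_linear(v, s) for n, v, s in zip(names, (k3, k4, N), se_log)},
        ssr=ssr,
        dof=dof,
        n_points=n_points,
        converged=converged,
        ambiguous=bool(flags),
        flags=flags,
    )
    Ki = k4 / k3
    return CompetitionFit(
        fit=fit,
        Ki=Ki,
        pKi=float(-np.log10(Ki)),
        k3=k3,
        k4=k4,
        residence_time=1.0 / k4,
    )


def fit_competition_rapid(
    traces: Sequence[KineticTrace],
    tracer: TracerKinetics,
    n_starts: int = 5,
) -> CompetitionFit:
    """Fit the rapid-competitor-dissociation model for Ki (and N).

    Appropriate when the competitor equilibrates with free receptor on a
    timescale much shorter than the tracer's; only the equilibrium
    affinity Ki is identifiable.
    """
    _check_competition_design(traces)
    names = ["Ki", "N"]

    def residual(x: np.ndarray) -> np.ndarray:
        Ki, N = 10.0 ** x
        tr_k = TracerKinetics(k1=tracer.k1, k2=tracer.k2, N=N)
        rc = RapidCompetitor(Ki=Ki)
        return np.concatenate(
            [
                rapid_competition_occupancy(tr.times, tr_k, rc, tr.L, tr.I) - tr.signal
                for tr in traces
            ]
        )

    starts = _competition_starts(traces, tracer, n_starts=n_starts, n_params=2)
    x, jac, converged = _multistart_lsq(residual, starts)
    Ki, N = 10.0 ** x
    ssr = float(np.sum(residual(x) ** 2))
    n_points = int(sum(len(tr.times) for tr in traces))
    dof = n_points - 2
    se_log = _se_from_jacobian(jac, ssr, dof)
    flags = _ambiguity_flags(x, se_log, names, converged)
    fit = FitResult(
        model=RAPID_DISSOCIATION,
        params={"Ki": Ki, "N": N},
        se={n: _log_se_to_linear(v, s) for n, v, s in zip(names, (Ki, N), se_log)},
        ssr=ssr,
        dof=dof,
        n_points=n_points,
        converged=converged,
        ambiguous=bool(flags),
        flags=flags,
    )
    return CompetitionFit(fit=fit, Ki=Ki, pKi=float(-np.log10(Ki)))


def compare_models(simple: FitResult, complex: FitResult, alpha: float = 0.05) -> ModelComparison:
    """Extra-sum-of-squares partial F-test between nested fits of the same data.

    F = ((SSR_s - SSR_c)/(dof_s - dof_c)) / (SSR_c/dof_c), upper-tail p
    from F(df_num, df_den).  The complex model is selected iff p < alpha.
    A negative numerator (simple fit better despite fewer parameters, a
    multistart artefact) clamps F to 0.
    """
    if simple.n_points != complex.n_points:
        raise ValueError("fits must be to the same data (n_points differ)")
    df_num = simple.dof - complex.dof
    df_den = complex.dof
    if df_num < 1:
        raise ValueError("simple model must have more residual degrees of freedom")
    if df_den < 1:
        raise ValueError("complex model has no residual degrees of freedom")
    num = (simple.ssr - complex.ssr) / df_num
    den = complex.ssr / df_den
    f = max(num / den, 0.0) if den > 0 else np.inf
    p = float(stats.f.sf(f, df_num, df_den))
    selected = complex.model if p < alpha else simple.model
    return ModelComparison(f_stat=float(f), p_value=p, df_num=df_num, df_den=df_den, selected=selected)


def fit_competition_auto(
    traces: Sequence[KineticTrace],
    tracer: TracerKinetics,
    alpha: float = 0.05,
    n_starts: int = 5,
) -> tuple[CompetitionFit, ModelComparison]:
    """Fit both competition models and select by partial F-test.

    Returns the selected fit and the comparison record.  The rapid model
    is the simpler null; the full model is retained only when its extra
    rate parameter significantly reduces the residual sum of squares.
    """
    rapid = fit_competition_rapid(traces, tracer, n_starts=n_starts)
    full = fit_competition_full(traces, tracer, n_starts=n_starts)
    cmp_ = compare_models(rapid.fit, full.fit, alpha=alpha)
    chosen = full if cmp_.selected == MOTULSKY_MAHAN else rapid
    if chosen is full and full.fit.ambiguous:
        warnings.warn("full model selected but flagged ambiguous", stacklevel=2)
    return chosen, cmp_
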