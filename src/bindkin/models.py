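"""Closed-form competition binding kinetics.

Two ligands — a labelled tracer L and an unlabelled competitor I — bind
reversibly and mutually exclusively to a single receptor site:

    R + L <-> RL   (k1, k2)
    R + I <-> RI   (k3, k4)

With ligand in excess (no depletion) the tracer occupancy [RL](t) after
simultaneous addition of both ligands to unoccupied receptor has the
bi-exponential closed form of Motulsky & Mahan.  When the competitor
dissociates much faster than the tracer it equilibrates essentially
instantly with the free receptor, and the tracer time course collapses to a
mono-exponential association scaled by the fraction of receptor the
competitor leaves free; that limit form estimates the competitor's
equilibrium affinity Ki but carries no information about its rates.

Units are molar and minutes throughout: association rate constants in
M^-1 min^-1, dissociation rate constants in min^-1, concentrations in M.
The maximal specific signal ``N`` (B_max) is in arbitrary signal units
(e.g. a baseline-corrected BRET ratio), not receptor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TracerKinetics",
    "CompetitorKinetics",
    "RapidCompetitor",
    "EigenRates",
    "KineticTrace",
    "eigen_rates",
    "motulsky_mahan_occupancy",
    "fractional_occupancy",
    "observed_association_rate",
    "rapid_competition_occupancy",
    "residence_time",
    "dissociation_halflife",
    "ode_occupancy",
]

# relative |KF-KS|/KF below which the repeated-root limit form is used
_REPEATED_ROOT_RTOL = 1e-9


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def _require_nonnegative(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(~np.isfinite(np.asarray(value, dtype=float))) or np.any(
            np.asarray(value, dtype=float) < 0
        ):
            raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class TracerKinetics:
    """Rate constants of the labelled tracer.

    Attributes
    ----------
    k1 : association rate constant (M^-1 min^-1)
    k2 : dissociation rate constant (min^-1)
    N : maximal specific signal B_max (signal units)
    """

    k1: float
    k2: float
    N: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k2=self.k2, N=self.N)

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant k2/k1 (M)."""
        return self.k2 / self.k1


@dataclass(frozen=True)
class CompetitorKinetics:
    """Rate constants of the unlabelled competitor.

    k3: association rate constant (M^-1 min^-1); k4: dissociation rate
    constant (min^-1).
    """

    k3: float
    k4: float

    def __post_init__(self) -> None:
        _require_positive(k3=self.k3, k4=self.k4)

    @property
    def Ki(self) -> float:
        """Equilibrium dissociation constant k4/k3 (M)."""
        return self.k4 / self.k3

    @property
    def pKi(self) -> float:
        return -np.log10(self.Ki)


@dataclass(frozen=True)
class RapidCompetitor:
    """Competitor characterised only by its equilibrium affinity Ki (M)."""

    Ki: float

    def __post_init__(self) -> None:
        _require_positive(Ki=self.Ki)

    @property
    def pKi(self) -> float:
        return -np.log10(self.Ki)


@dataclass(frozen=True)
class EigenRates:
    """Observed fast/slow rates of the two-ligand competition system.

    KA = [L]k1 + k2 and KB = [I]k3 + k4 are the single-ligand observed
    rates; KF and KS are the eigenvalues of the coupled system and satisfy
    KF + KS = KA + KB and KF*KS = k2*k4 + k2*k3[I] + k4*k1[L].
    """

    KA: float
    KB: float
    KF: float
    KS: float


@dataclass
class KineticTrace:
    """One well's time course of specific tracer binding.

    times are minutes (strictly increasing, >= 0), signal is specific
    binding in signal units, L/I are the tracer and competitor
    concentrations in M.
    """

    times: np.ndarray
    signal: np.ndarray
    L: float
    I: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.signal.shape != self.times.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        _require_positive(L=self.L)
        _require_nonnegative(I=self.I)


def eigen_rates(tracer: TracerKinetics, comp: CompetitorKinetics, L: float, I: float) -> EigenRates:
    """Fast and slow observed rates (min^-1) of the coupled two-ligand system."""
    _require_positive(L=L)
    _require_nonnegative(I=I)
    KA = L * tracer.k1 + tracer.k2
    KB = I * comp.k3 + comp.k4
    disc = np.sqrt((KA - KB) ** 2 + 4.0 * L * I * tracer.k1 * comp.k3)
    KF = 0.5 * (KA + KB + disc)
    KS = 0.5 * (KA + KB - disc)
    return EigenRates(KA=KA, KB=KB, KF=KF, KS=KS)


def motulsky_mahan_occupancy(
    t,
    tracer: TracerKinetics,
    comp: CompetitorKinetics,
    L: float,
    I: float,
):
    """Specific tracer binding [RL](t) under simultaneous two-ligand competition.

    Evaluates the bi-exponential closed form

        [RL]_t = N[L]k1/(KF-KS) * [ k4(KF-KS)/(KF*KS)
                                    - (k4-KS)/KS * exp(-KS t)
                                    + (k4-KF)/KF * exp(-KF t) ]

    switching to the analytic repeated-root limit when KF and KS coincide
    to within numerical tolerance (the generic form is 0/0 there).

    Parameters are in M and minutes; returns signal units (same scale as
    ``tracer.N``).  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    _require_nonnegative(t=t)
    rates = eigen_rates(tracer, comp, L, I)
    KF, KS = rates.KF, rates.KS
    k1, k2, N = tracer.k1, tracer.k2, tracer.N
    k4 = comp.k4

    if (KF - KS) / KF < _REPEATED_ROOT_RTOL:
        # L'Hopital limit at KF == KS == K:
        # [RL]_t = N[L]k1 * { k4/K^2 - exp(-Kt) [ k4/K^2 + t(k4-K)/K ] }
        K = 0.5 * (KF + KS)
        out = N * L * k1 * (
            k4 / K**2 - np.exp(-K * t) * (k4 / K**2 + t * (k4 - K) / K)
        )
    else:
        out = (
            N
            * L
            * k1
            / (KF - KS)
            * (
                k4 * (KF - KS) / (KF * KS)
                - (k4 - KS) / KS * np.exp(-KS * t)
                + (k4 - KF) / KF * np.exp(-KF * t)
            )
        )
    # tiny negative values from cancellation at t ~ 0
    return np.clip(out, 0.0, None) if out.ndim else float(max(out, 0.0))


def fractional_occupancy(I: float, Ki: float):
    """Equilibrium fraction of free receptor occupied by competitor.

    rho_I = [I] / (Ki + [I]); in [0, 1), monotone nondecreasing in I.
    """
    _require_positive(Ki=Ki)
    _require_nonnegative(I=I)
    I = np.asarray(I, dtype=float)
    out = I / (Ki + I)
    return float(out) if out.ndim == 0 else out


def observed_association_rate(L: float, tracer: TracerKinetics, rho: float) -> float:
    """Observed tracer association rate in the presence of competitor.

    k_obs,+I = [L]k1(1 - rho_I) + k2  (min^-1).  rho is the competitor's
    fractional occupancy of tracer-free receptor, in [0, 1).
    """
    _require_positive(L=L)
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho!r}")
    return L * tracer.k1 * (1.0 - rho) + tracer.k2


def rapid_competition_occupancy(
    t,
    tracer: TracerKinetics,
    rc: RapidCompetitor,
    L: float,
    I: float,
):
    """Tracer binding when the competitor equilibrates instantly.

    [RL]_t = N[L]k1(1-rho_I)/k_obs,+I * (1 - exp(-k_obs,+I t))

    Mono-exponential in t; plateau N[L]k1(1-rho_I)/k_obs,+I.  Only the
    competitor's equilibrium affinity enters, via rho_I = I/(Ki+I).
    """
    t = np.asarray(t, dtype=float)
    _require_nonnegative(t=t)
    rho = fractional_occupancy(I, rc.Ki)
    kobs = observed_association_rate(L, tracer, rho)
    out = tracer.N * L * tracer.k1 * (1.0 - rho) / kobs * (1.0 - np.exp(-kobs * t))
    return float(out) if out.ndim == 0 else out


def residence_time(koff: float) -> float:
    """Mean receptor-ligand complex lifetime RT = 1/koff (min)."""
    _require_positive(koff=koff)
    return 1.0 / koff


def dissociation_halflife(koff: float) -> float:
    """Dissociation half-life ln(2)/koff (min)."""
    _require_positive(koff=koff)
    return np.log(2.0) / koff


def ode_occupancy(
    t,
    tracer: TracerKinetics,
    comp: CompetitorKinetics,
    L: float,
    I: float,
    rtol: float = 1e-10,
    atol: float = 1e-14,
):
    """Numerical oracle: integrate the two-ligand mass-action system.

        dRL/dt = k1[L](N - RL - RI) - k2 RL
        dRI/dt = k3[I](N - RL - RI) - k4 RI

    Receptor is conserved (R = N - RL - RI) and free ligand is not
    depleted, matching the closed form's assumptions.  Used for validating
    :func:`motulsky_mahan_occupancy`, not for fitting.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    _require_nonnegative(t=t)
    k1, k2, N = tracer.k1, tracer.k2, tracer.N
    k3, k4 = comp.k3, comp.k4

    def rhs(_t, y):
        RL, RI = y
        free = N - RL - RI
        return [k1 * L * free - k2 * RL, k3 * I * free - k4 * RI]

    t_end = float(t.max()) if t.size else 0.0
    if t_end == 0.0:
        return np.zeros_like(t)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]
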