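"""Synthetic plate data with known ground truth.

Generators for every fitting stage: kinetic competition plates
(bi-exponential specific binding plus additive Gaussian plate noise and a
constant nonspecific-binding floor), sigmoidal dose-response plates, and
first-order depletion series.  Each generator returns the data together
with a JSON-serialisable ground-truth record so that recovery tests never
rely on hard-coded numbers.

The default kinetic fixture reproduces a slow-dissociating antagonist
measured against a fluorescent tracer: tracer k1 = 2.86e7 M^-1 min^-1,
k2 = 0.4397 min^-1 at 5 nM, competitor k3 = 3.25e8 M^-1 min^-1,
k4 = 0.0248 min^-1, read over 0-60 min.  With k4 << k2 this produces the
classic tracer overshoot at intermediate competitor concentrations.

Noise is additive Gaussian on the signal (BRET-ratio-like) scale:
ratiometric reads have roughly constant noise, so proportional noise is
available but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    TracerKinetics,
    CompetitorKinetics,
    RapidCompetitor,
    KineticTrace,
    motulsky_mahan_occupancy,
    rapid_competition_occupancy,
)
from .equilibrium import _logistic
from .pk import DepletionSeries

__all__ = [
    "NoiseModel",
    "PlateDesign",
    "mrs1220_fixture",
    "gen_competition_plate",
    "gen_dose_response",
    "gen_depletion",
    "gaddum_ec50",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise: sd_abs in signal units; optional proportional term."""

    sd_abs: float = 0.0
    sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_abs < 0 or self.sd_rel < 0:
            raise ValueError("noise SDs must be non-negative")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd_abs == 0 and self.sd_rel == 0:
            return np.asarray(clean, dtype=float).copy()
        sd = np.sqrt(self.sd_abs**2 + (self.sd_rel * np.asarray(clean)) ** 2)
        return clean + rng.normal(0.0, 1.0, np.shape(clean)) * sd


@dataclass(frozen=True)
class PlateDesign:
    """Layout of a kinetic competition plate.

    competitor_concs must include 0 (tracer-only control); an NSB well
    (saturating competitor, constant baseline) is always added.
    """

    tracer_conc: float
    competitor_concs: tuple
    times: tuple
    replicates: int = 1
    nsb_level: float = 0.0

    def __post_init__(self) -> None:
        if self.tracer_conc <= 0:
            raise ValueError("tracer_conc must be positive")
        if 0.0 not in self.competitor_concs:
            raise ValueError("design must include the I=0 control well")
        if len(self.times) < 2:
            raise ValueError("need >= 2 time points")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def mrs1220_fixture() -> tuple[TracerKinetics, CompetitorKinetics, PlateDesign]:
    """Default slow-dissociation fixture (tracer at 5 nM, 0-60 min reads)."""
    tracer = TracerKinetics(k1=2.86e7, k2=0.4397, N=1.0)
    comp = CompetitorKinetics(k3=3.25e8, k4=0.0248)
    design = PlateDesign(
        tracer_conc=5e-9,
        competitor_concs=(0.0, 1e-9, 3e-9, 1e-8, 3e-8),
        times=tuple(np.linspace(0.0, 60.0, 25)),
    )
    return tracer, comp, design


def gen_competition_plate(
    tracer: TracerKinetics,
    truth: CompetitorKinetics | RapidCompetitor,
    design: PlateDesign,
    noise: NoiseModel = NoiseModel(),
) -> tuple[list[KineticTrace], dict]:
    """Simulate one kinetic competition plate.

    Traces follow the full two-ligand model when ``truth`` carries rate
    constants, or the rapid-equilibration model when it carries only Ki.
    An NSB well (constant ``design.nsb_level``) is appended.  Returns
    (traces, truth_record); the record holds every generating parameter.
    """
    rng = np.random.default_rng(noise.seed)
    t = np.asarray(design.times, dtype=float)
    L = design.tracer_conc
    traces: list[KineticTrace] = []
    for I in design.competitor_concs:
        if isinstance(truth, CompetitorKinetics):
            clean = motulsky_mahan_occupancy(t, tracer, truth, L, I)
        else:
            clean = rapid_competition_occupancy(t, tracer, truth, L, I)
        for rep in range(design.replicates):
            traces.append(
                KineticTrace(
                    times=t,
                    signal=noise.apply(clean, rng),
                    L=L,
                    I=I,
                    meta={"rep": rep, "is_nsb": False},
                )
            )
    for rep in range(design.replicates):
        nsb = np.full_like(t, design.nsb_level)
        traces.append(
            KineticTrace(
                times=t,
                signal=noise.apply(nsb, rng),
                L=L,
                I=1e-4,  # saturating competitor defines the NSB floor
                meta={"rep": rep, "is_nsb": True},
            )
        )
    record: dict = {
        "model": "motulsky_mahan" if isinstance(truth, CompetitorKinetics) else "rapid_dissociation",
        "tracer": {"k1": tracer.k1, "k2": tracer.k2, "N": tracer.N},
        "L": L,
        "competitor_concs": list(design.competitor_concs),
        "noise": {"sd_abs": noise.sd_abs, "sd_rel": noise.sd_rel, "seed": noise.seed},
        "nsb_level": design.nsb_level,
    }
    if isinstance(truth, CompetitorKinetics):
        record["competitor"] = {"k3": truth.k3, "k4": truth.k4, "Ki": truth.Ki}
    else:
        record["competitor"] = {"Ki": truth.Ki}
    return traces, record


def gaddum_ec50(ec50_control: float, B: float, KB: float) -> float:
    """Agonist EC50 shifted by a competitive antagonist: EC50*(1 + [B]/KB)."""
    if ec50_control <= 0 or KB <= 0 or B < 0:
        raise ValueError("concentrations and KB must be positive (B >= 0)")
    return ec50_control * (1.0 + B / KB)


def gen_dose_response(
    p50: float,
    concs,
    top: float = 100.0,
    bottom: float = 0.0,
    direction: str = "inhibition",
    hill: float = 1.0,
    noise: NoiseModel = NoiseModel(),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a sigmoidal dose-response series.

    p50 is -log10(EC50 or IC50).  Returns (concs, responses, truth_record).
    """
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    s = hill if direction == "stimulation" else -hill
    clean = _logistic(np.log10(concs), top, bottom, -p50, s)
    rng = np.random.default_rng(noise.seed)
    resp = noise.apply(clean, rng)
    record = {
        "p50": p50,
        "top": top,
        "bottom": bottom,
        "direction": direction,
        "hill": hill,
        "noise": {"sd_abs": noise.sd_abs, "sd_rel": noise.sd_rel, "seed": noise.seed},
    }
    return concs, resp, record


def gen_depletion(
    k: float,
    times,
    noise: NoiseModel = NoiseModel(),
    matrix: str = "microsome",
    protein_conc: float | None = None,
) -> tuple[DepletionSeries, dict]:
    """Simulate a first-order depletion series: pct(t) = 100*exp(k*t), k <= 0."""
    if k > 0:
        raise ValueError("depletion rate k must be <= 0")
    times = np.asarray(times, dtype=float)
    clean = 100.0 * np.exp(k * times)
    rng = np.random.default_rng(noise.seed)
    pct = noise.apply(clean, rng)
    series = DepletionSeries(
        times=times, pct_remaining=pct, matrix=matrix, protein_conc=protein_conc
    )
    record = {
        "k": k,
        "matrix": matrix,
        "protein_conc": protein_conc,
        "noise": {"sd_abs": noise.sd_abs, "sd_rel": noise.sd_rel, "seed": noise.seed},
    }
    return series, record
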