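import numpy as np
import pytest

from bindkin.models import TracerKinetics, CompetitorKinetics, KineticTrace
from bindkin.synthetic import PlateDesign


@pytest.fixture(scope="session")
def tracer():
    """Slow-off fluorescent tracer used throughout (k1, k2 in M^-1min^-1, min^-1)."""
    return TracerKinetics(k1=2.86e7, k2=0.4397, N=1.0)


@pytest.fixture(scope="session")
def slow_competitor():
    """Slow-dissociating competitor (k4 << tracer k2): produces overshoot."""
    return CompetitorKinetics(k3=3.25e8, k4=0.0248)


@pytest.fixture(scope="session")
def plate_design():
    return PlateDesign(
        tracer_conc=5e-9,
        competitor_concs=(0.0, 1e-9, 3e-9, 1e-8, 3e-8),
        times=tuple(np.linspace(0.0, 60.0, 25)),
    )


@pytest.fixture
def tracer_only_traces(tracer):
    """Noise-free mono-exponential association traces at four tracer concentrations."""
    t = np.linspace(0.0, 10.0, 12)
    traces = []
    for L in (5e-9, 10e-9, 20e-9, 40e-9):
        kobs = L * tracer.k1 + tracer.k2
        y = tracer.N * L * tracer.k1 / kobs * (1.0 - np.exp(-kobs * t))
        traces.append(KineticTrace(times=t, signal=y, L=L))
    return traces
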