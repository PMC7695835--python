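import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkin.models import (
    TracerKinetics,
    CompetitorKinetics,
    RapidCompetitor,
    KineticTrace,
    eigen_rates,
    motulsky_mahan_occupancy,
    rapid_competition_occupancy,
    fractional_occupancy,
    observed_association_rate,
    residence_time,
    dissociation_halflife,
    ode_occupancy,
)

log_rate = st.floats(min_value=-2.0, max_value=2.0)
log_conc = st.floats(min_value=-10.0, max_value=-5.0)


class TestClosedForm:
    def test_zero_at_time_zero(self, tracer, slow_competitor):
        assert motulsky_mahan_occupancy(0.0, tracer, slow_competitor, 5e-9, 1e-8) == 0.0
        rc = RapidCompetitor(Ki=1e-8)
        assert rapid_competition_occupancy(0.0, tracer, rc, 5e-9, 1e-8) == 0.0

    def test_plateau_without_competitor(self, tracer, slow_competitor):
        """As t -> inf with I=0 the occupancy tends to L*k1/(L*k1 + k2)."""
        L = 5e-9
        expected = L * tracer.k1 / (L * tracer.k1 + tracer.k2)
        val = motulsky_mahan_occupancy(1e4, tracer, slow_competitor, L, 0.0)
        assert val == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.2454, abs=5e-4)

    def test_matches_ode_oracle_on_reference_parameters(self, tracer, slow_competitor):
        t = np.linspace(0.0, 60.0, 40)[1:]
        closed = motulsky_mahan_occupancy(t, tracer, slow_competitor, 5e-9, 1e-8)
        numeric = ode_occupancy(t, tracer, slow_competitor, 5e-9, 1e-8)
        assert np.max(np.abs(closed - numeric) / numeric) < 1e-6

    def test_matches_ode_oracle_random_parameters(self):
        """Closed form vs mass-action integration over random rate/concentration draws."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            tr = TracerKinetics(
                k1=10 ** rng.uniform(5, 9), k2=10 ** rng.uniform(-2, 1), N=10 ** rng.uniform(-1, 1)
            )
            co = CompetitorKinetics(k3=10 ** rng.uniform(5, 9), k4=10 ** rng.uniform(-2, 1))
            L = 10 ** rng.uniform(-10, -5)
            I = 10 ** rng.uniform(-10, -5)
            t = np.linspace(0.0, 30.0, 16)[1:]
            closed = motulsky_mahan_occupancy(t, tr, co, L, I)
            numeric = ode_occupancy(t, tr, co, L, I)
            scale = np.maximum(np.abs(numeric), tr.N * 1e-12)
            worst = max(worst, float(np.max(np.abs(closed - numeric) / scale)))
        assert worst < 1e-5

    def test_bounded_above_by_N(self, tracer, slow_competitor):
        t = np.linspace(0.0, 200.0, 500)
        y = motulsky_mahan_occupancy(t, tracer, slow_competitor, 5e-9, 1e-8)
        assert np.all(y <= tracer.N)
        assert np.all(y >= 0)

    def test_mono_exponential_reduction_at_zero_competitor(self, tracer, slow_competitor):
        """Both models collapse to the same mono-exponential when I = 0."""
        t = np.linspace(0.0, 20.0, 50)
        L = 5e-9
        kobs = L * tracer.k1 + tracer.k2
        mono = tracer.N * L * tracer.k1 / kobs * (1.0 - np.exp(-kobs * t))
        full = motulsky_mahan_occupancy(t, tracer, slow_competitor, L, 0.0)
        rapid = rapid_competition_occupancy(t, tracer, RapidCompetitor(Ki=1e-8), L, 0.0)
        np.testing.assert_allclose(full, mono, rtol=1e-9)
        np.testing.assert_allclose(rapid, mono, rtol=1e-12)

    def test_repeated_root_limit_is_continuous(self):
        """The KF == KS limit form joins the generic expression smoothly."""
        # KA = KB = 1.0 and I -> 0 collapses the discriminant: repeated root
        tr = TracerKinetics(k1=1e7, k2=0.5, N=1.0)
        L = 5e-8  # KA = 1.0
        t = np.linspace(0.0, 10.0, 30)
        co = CompetitorKinetics(k3=1e7, k4=1.0)  # KB = 1.0 at I ~ 0
        y_limit = motulsky_mahan_occupancy(t, tr, co, L, 1e-30)  # repeated-root branch
        y_near = motulsky_mahan_occupancy(t, tr, co, L, 1e-16)  # generic branch
        y_mono = tr.N * L * tr.k1 / 1.0 * (1.0 - np.exp(-1.0 * t))
        np.testing.assert_allclose(y_limit, y_mono, rtol=1e-9)
        np.testing.assert_allclose(y_near, y_limit, rtol=1e-6)

    def test_domain_errors(self, tracer, slow_competitor):
        with pytest.raises(ValueError):
            motulsky_mahan_occupancy(-1.0, tracer, slow_competitor, 5e-9, 0.0)
        with pytest.raises(ValueError):
            motulsky_mahan_occupancy(1.0, tracer, slow_competitor, -5e-9, 0.0)
        with pytest.raises(ValueError):
            TracerKinetics(k1=-1.0, k2=0.4, N=1.0)
        with pytest.raises(ValueError):
            CompetitorKinetics(k3=1e8, k4=0.0)


class TestRapidLimit:
    def test_rapid_model_is_fast_dissociation_limit(self, tracer):
        """Deviation from the full model shrinks monotonically as k4 grows."""
        Ki = 0.0248 / 3.25e8
        rc = RapidCompetitor(Ki=Ki)
        t = np.linspace(0.1, 60.0, 120)
        devs = []
        for k4 in (1e2, 1e3, 1e4):
            co = CompetitorKinetics(k3=k4 / Ki, k4=k4)
            full = motulsky_mahan_occupancy(t, tracer, co, 5e-9, 1e-8)
            rapid = rapid_competition_occupancy(t, tracer, rc, 5e-9, 1e-8)
            devs.append(float(np.max(np.abs(full - rapid) / rapid)))
        assert devs[0] > devs[1] > devs[2]
        assert devs[1] < 0.01

    def test_rapid_plateau(self, tracer):
        rc = RapidCompetitor(Ki=1e-8)
        L, I = 5e-9, 1e-8
        rho = fractional_occupancy(I, rc.Ki)
        kobs = observed_association_rate(L, tracer, rho)
        plateau = tracer.N * L * tracer.k1 * (1 - rho) / kobs
        assert rapid_competition_occupancy(1e4, tracer, rc, L, I) == pytest.approx(plateau, rel=1e-12)

    def test_infinite_competitor_suppresses_binding(self, tracer):
        rc = RapidCompetitor(Ki=1e-9)
        y = rapid_competition_occupancy(np.linspace(0, 60, 10), tracer, rc, 5e-9, 1.0)
        assert np.all(y < 1e-6)


class TestOvershoot:
    @staticmethod
    def _has_interior_max(y):
        imax = int(np.argmax(y))
        return 0 < imax < len(y) - 1 and y[imax] > y[-1] * (1 + 1e-6)

    def test_overshoot_iff_competitor_slower_than_tracer(self, tracer):
        """Interior maximum in the trace appears exactly when k4 < k2."""
        t = np.linspace(0.0, 300.0, 1500)
        Ki_vals = {0.0248: True, 0.4397 * 10: False, 5.0: False}
        for k4, expect in Ki_vals.items():
            co = CompetitorKinetics(k3=3.25e8, k4=k4)
            y = motulsky_mahan_occupancy(t, tracer, co, 5e-9, 10 * co.Ki)
            assert self._has_interior_max(y) == expect, f"k4={k4}"

    def test_rapid_model_is_always_monotone(self, tracer):
        t = np.linspace(0.0, 300.0, 1500)
        for Ki in (1e-9, 1e-8, 1e-7):
            y = rapid_competition_occupancy(t, tracer, RapidCompetitor(Ki=Ki), 5e-9, 10 * Ki)
            assert np.all(np.diff(y) >= -1e-15)


class TestEigenRates:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(lk1=log_rate, lk2=log_rate, lk3=log_rate, lk4=log_rate, lL=log_conc, lI=log_conc)
    def test_algebraic_identities(self, lk1, lk2, lk3, lk4, lL, lI):
        """KF+KS = KA+KB and KF*KS = k2k4 + k2k3[I] + k4k1[L], to machine precision."""
        tr = TracerKinetics(k1=10 ** (lk1 + 7), k2=10**lk2, N=1.0)
        co = CompetitorKinetics(k3=10 ** (lk3 + 7), k4=10**lk4)
        L, I = 10**lL, 10**lI
        r = eigen_rates(tr, co, L, I)
        assert r.KF >= r.KS > 0
        assert r.KF + r.KS == pytest.approx(r.KA + r.KB, rel=1e-12)
        expected_product = tr.k2 * co.k4 + tr.k2 * co.k3 * I + co.k4 * tr.k1 * L
        assert r.KF * r.KS == pytest.approx(expected_product, rel=1e-9)


class TestScalars:
    @pytest.mark.parametrize(
        "I, Ki, expected",
        [(0.0, 1e-8, 0.0), (1e-8, 1e-8, 0.5), (9e-8, 1e-8, 0.9)],
    )
    def test_fractional_occupancy(self, I, Ki, expected):
        assert fractional_occupancy(I, Ki) == pytest.approx(expected, abs=1e-12)

    def test_fractional_occupancy_monotone_and_bounded(self):
        I = np.logspace(-12, -3, 50)
        rho = fractional_occupancy(I, 1e-8)
        assert np.all(np.diff(rho) > 0)
        assert np.all((rho >= 0) & (rho < 1))

    def test_fractional_occupancy_domain(self):
        with pytest.raises(ValueError):
            fractional_occupancy(1e-8, 0.0)

    def test_observed_association_rate(self, tracer):
        assert observed_association_rate(5e-9, tracer, 0.0) == pytest.approx(0.5827)
        assert observed_association_rate(5e-9, tracer, 0.5) == pytest.approx(0.5112)
        # rho -> 1: tracer blocked, rate tends to k2
        assert observed_association_rate(5e-9, tracer, 1 - 1e-12) == pytest.approx(tracer.k2)
        with pytest.raises(ValueError):
            observed_association_rate(5e-9, tracer, 1.0)

    def test_residence_time(self):
        assert residence_time(0.0248) == pytest.approx(40.32, abs=5e-3)
        assert residence_time(1.0) == 1.0
        with pytest.raises(ValueError):
            residence_time(0.0)

    def test_dissociation_halflife(self):
        # koff = 1 min^-1 corresponds to ~41.6 s, under the 42 s mark
        assert dissociation_halflife(1.0) * 60 == pytest.approx(41.59, abs=5e-3)
        assert dissociation_halflife(1.0) * 60 < 42.0
        assert dissociation_halflife(0.0248) == pytest.approx(residence_time(0.0248) * np.log(2))


class TestKineticTrace:
    def test_validation(self):
        with pytest.raises(ValueError):
            KineticTrace(times=[0, 1, 1], signal=[0, 1, 2], L=5e-9)
        with pytest.raises(ValueError):
            KineticTrace(times=[0, 1], signal=[0, 1, 2], L=5e-9)
        with pytest.raises(ValueError):
            KineticTrace(times=[0, 1], signal=[0, 1], L=0.0)
        tr = KineticTrace(times=[0, 1], signal=[0, 1], L=5e-9)
        assert tr.I == 0.0
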