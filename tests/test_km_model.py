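import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuelight.exceptions import (
    InvalidParameterError,
    KMInapplicableError,
    NonPhysicalMeasurementError,
)
from tissuelight.km_model import (
    DiffuseMeasurement,
    KMCoefficients,
    OpticalProperties,
    effective_attenuation,
    estimate_optical_properties,
    forward_km,
    invert_km,
    km_to_transport,
    penetration_depth,
    transport_to_km,
)

# frozen oracle: high-precision evaluation of the closed form at
# s=10, a=1, D=0.1 (X=1.1, Y=sqrt(0.21))
ORACLE_R = 0.46103362327732366963
ORACLE_T = 0.44528421326396147928

S_GRID = [0.5, 1.0, 5.0, 10.0, 30.0, 50.0]
A_GRID = [0.0, 0.1, 1.0, 5.0]
D_GRID = [0.01, 0.1, 0.3]


class TestForwardKM:
    def test_zero_absorption_limit(self):
        # SD = 1 => R = T = 1/2
        r, t = forward_km(10.0, 0.0, 0.1)
        assert r == pytest.approx(0.5, rel=1e-12)
        assert t == pytest.approx(0.5, rel=1e-12)

    def test_oracle_value(self):
        r, t = forward_km(10.0, 1.0, 0.1)
        assert r == pytest.approx(ORACLE_R, rel=1e-12)
        assert t == pytest.approx(ORACLE_T, rel=1e-12)

    def test_x_recovered_from_forward_values(self):
        r, t = forward_km(10.0, 1.0, 0.1)
        x = (1.0 + r * r - t * t) / (2.0 * r)
        assert x == pytest.approx(1.1, rel=1e-12)

    def test_vanishing_slab_transmits_everything(self):
        r, t = forward_km(10.0, 1.0, 1e-9)
        assert r == pytest.approx(0.0, abs=1e-7)
        assert t == pytest.approx(1.0, abs=1e-7)

    def test_overflow_branch(self):
        s, a, d = 50.0, 5.0, 1e4  # s*Y*D far beyond hyperbolic overflow
        r, t = forward_km(s, a, d)
        x = 1.0 + a / s
        y = math.sqrt(x * x - 1.0)
        assert r == pytest.approx(1.0 / (x + y), rel=1e-12)
        assert t == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("bad", [(-1.0, 0.0, 0.1), (0.0, 0.0, 0.1),
                                     (10.0, -1.0, 0.1), (10.0, 1.0, 0.0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            forward_km(*bad)

    @pytest.mark.parametrize("s", S_GRID)
    @pytest.mark.parametrize("a", A_GRID)
    @pytest.mark.parametrize("d", D_GRID)
    def test_energy_balance(self, s, a, d):
        r, t = forward_km(s, a, d)
        assert 0.0 < r < 1.0
        assert 0.0 < t < 1.0
        absorbed = 1.0 - r - t
        if a == 0.0:
            assert absorbed == pytest.approx(0.0, abs=1e-12)
        else:
            assert absorbed > 0.0

    def test_monotonic_in_s(self):
        rs = [forward_km(s, 1.0, 0.1)[0] for s in S_GRID]
        assert all(b > a for a, b in zip(rs, rs[1:]))

    def test_monotonic_in_a(self):
        ts = [forward_km(10.0, a, 0.1)[1] for a in A_GRID]
        assert all(b < a for a, b in zip(ts, ts[1:]))


class TestInvertKM:
    def test_zero_absorption_branch(self):
        k = invert_km(DiffuseMeasurement(r_d=0.5, t_d=0.5, thickness_cm=0.1))
        assert k.s_km == pytest.approx(10.0, rel=1e-9)
        assert k.a_km == 0.0
        assert k.x == 1.0

    def test_oracle_inverse(self):
        k = invert_km(
            DiffuseMeasurement(r_d=ORACLE_R, t_d=ORACLE_T, thickness_cm=0.1)
        )
        assert k.s_km == pytest.approx(10.0, rel=1e-9)
        assert k.a_km == pytest.approx(1.0, rel=1e-9)
        assert k.x == pytest.approx(1.1, rel=1e-9)
        assert k.y == pytest.approx(math.sqrt(k.x**2 - 1.0), rel=1e-12)

    def test_non_physical_measurement(self):
        with pytest.raises(NonPhysicalMeasurementError):
            invert_km(DiffuseMeasurement(r_d=0.6, t_d=0.5, thickness_cm=0.1))

    def test_degenerate_reflectance_rejected_by_type(self):
        with pytest.raises(InvalidParameterError):
            DiffuseMeasurement(r_d=0.0, t_d=0.5, thickness_cm=0.1)

    def test_forward_reproduces_measurement(self):
        k = invert_km(
            DiffuseMeasurement(r_d=ORACLE_R, t_d=ORACLE_T, thickness_cm=0.1)
        )
        r, t = forward_km(k.s_km, k.a_km, 0.1)
        assert r == pytest.approx(ORACLE_R, abs=1e-9)
        assert t == pytest.approx(ORACLE_T, abs=1e-9)

    @pytest.mark.parametrize("s", S_GRID)
    @pytest.mark.parametrize("a", A_GRID)
    @pytest.mark.parametrize("d", D_GRID)
    def test_round_trip_grid(self, s, a, d):
        r, t = forward_km(s, a, d)
        k = invert_km(DiffuseMeasurement(r_d=r, t_d=t, thickness_cm=d))
        assert k.s_km == pytest.approx(s, rel=1e-6)
        assert k.a_km == pytest.approx(a, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("s", S_GRID)
    @pytest.mark.parametrize("a", [0.1, 1.0, 5.0])
    def test_x_consistency(self, s, a):
        # X recomputed from forward fractions equals 1 + a/s
        r, t = forward_km(s, a, 0.1)
        x = (1.0 + r * r - t * t) / (2.0 * r)
        assert x == pytest.approx(1.0 + a / s, rel=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(
        s=st.floats(0.3, 80.0),
        a=st.floats(0.0, 8.0),
        d=st.floats(0.01, 0.5),
    )
    def test_round_trip_property(self, s, a, d):
        r, t = forward_km(s, a, d)
        if not (0 < r < 1 and 0 < t < 1):
            return
        k = invert_km(DiffuseMeasurement(r_d=r, t_d=t, thickness_cm=d))
        assert k.s_km == pytest.approx(s, rel=1e-5)
        assert k.a_km == pytest.approx(a, rel=1e-5, abs=1e-5)


class TestTransportConversion:
    def test_km_to_transport_example(self):
        k = KMCoefficients.from_s_a(10.0, 1.0)
        p = km_to_transport(k)
        assert p.mu_a == pytest.approx(0.5, rel=1e-12)
        assert p.mu_s_prime == pytest.approx(13.5, rel=1e-12)

    def test_zero_absorption(self):
        p = km_to_transport(KMCoefficients.from_s_a(9.0, 0.0))
        assert p.mu_a == 0.0
        assert p.mu_s_prime == pytest.approx(12.0, rel=1e-12)

    def test_transport_to_km_example(self):
        k = transport_to_km(
            OpticalProperties(mu_a=0.5, mu_s_prime=13.5, thickness_cm=0.1)
        )
        assert k.s_km == pytest.approx(10.0, rel=1e-12)
        assert k.a_km == pytest.approx(1.0, rel=1e-12)

    def test_inapplicable_error(self):
        with pytest.raises(KMInapplicableError):
            transport_to_km(
                OpticalProperties(mu_a=3.0, mu_s_prime=1.0, thickness_cm=0.1)
            )

    @pytest.mark.parametrize("s,a", [(10.0, 1.0), (0.5, 0.1), (50.0, 5.0)])
    def test_round_trip_identity(self, s, a):
        k = KMCoefficients.from_s_a(s, a)
        k2 = transport_to_km(km_to_transport(k))
        assert k2.s_km == pytest.approx(k.s_km, rel=1e-12)
        assert k2.a_km == pytest.approx(k.a_km, rel=1e-12)


class TestPenetrationDepth:
    def test_example(self):
        p = OpticalProperties(mu_a=0.5, mu_s_prime=13.5, thickness_cm=0.1)
        assert penetration_depth(p) == pytest.approx(1.0 / math.sqrt(21.0), rel=1e-12)

    def test_pure_absorber_limit(self):
        mu = 2.0
        p = OpticalProperties(mu_a=mu, mu_s_prime=0.0, thickness_cm=0.1)
        assert penetration_depth(p) == pytest.approx(1.0 / (mu * math.sqrt(3.0)))

    def test_monotone_in_scattering(self):
        d9 = penetration_depth(
            OpticalProperties(mu_a=0.5, mu_s_prime=9.0, thickness_cm=0.1)
        )
        d37 = penetration_depth(
            OpticalProperties(mu_a=0.5, mu_s_prime=37.0, thickness_cm=0.1)
        )
        assert d9 > d37

    def test_zero_absorption_sentinel(self):
        p = OpticalProperties(mu_a=0.0, mu_s_prime=10.0, thickness_cm=0.1)
        with pytest.warns(RuntimeWarning):
            assert penetration_depth(p) == math.inf

    def test_reciprocal_of_effective_attenuation(self):
        p = OpticalProperties(mu_a=0.8, mu_s_prime=12.0, thickness_cm=0.2)
        assert penetration_depth(p) * effective_attenuation(p) == pytest.approx(
            1.0, rel=1e-12
        )


class TestEstimateOpticalProperties:
    def test_zero_absorption_chain(self):
        p = estimate_optical_properties(
            DiffuseMeasurement(r_d=0.5, t_d=0.5, thickness_cm=0.1)
        )
        assert p.mu_a == 0.0
        assert p.mu_s_prime == pytest.approx(40.0 / 3.0, rel=1e-9)

    def test_chained_oracle(self):
        p = estimate_optical_properties(
            DiffuseMeasurement(r_d=ORACLE_R, t_d=ORACLE_T, thickness_cm=0.1)
        )
        assert p.mu_a == pytest.approx(0.5, rel=1e-9)
        assert p.mu_s_prime == pytest.approx(13.5, rel=1e-9)

    def test_round_trip_from_transport(self):
        truth = OpticalProperties(mu_a=0.8, mu_s_prime=12.0, thickness_cm=0.2)
        k = transport_to_km(truth)
        r, t = forward_km(k.s_km, k.a_km, truth.thickness_cm)
        rec = estimate_optical_properties(
            DiffuseMeasurement(
                r_d=r, t_d=t, thickness_cm=truth.thickness_cm, power_mw=150.0
            )
        )
        assert rec.mu_a == pytest.approx(truth.mu_a, rel=1e-6)
        assert rec.mu_s_prime == pytest.approx(truth.mu_s_prime, rel=1e-6)
        assert rec.power_mw == 150.0
        assert rec.thickness_cm == truth.thickness_cm


class TestOpticalPropertiesType:
    def test_mu_s_prime_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            OpticalProperties(
                mu_a=0.5, mu_s_prime=10.0, thickness_cm=0.1, g=0.9, mu_s=50.0
            )

    def test_consistent_mu_s_accepted(self):
        p = OpticalProperties(
            mu_a=0.5, mu_s_prime=5.0, thickness_cm=0.1, g=0.9, mu_s=50.0
        )
        assert p.mu_s_prime == pytest.approx(p.mu_s * (1 - p.g), rel=1e-12)

    @pytest.mark.parametrize("g", [-1.0, 1.0, 1.5])
    def test_g_range(self, g):
        with pytest.raises(InvalidParameterError):
            OpticalProperties(mu_a=0.5, mu_s_prime=10.0, thickness_cm=0.1, g=g)
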