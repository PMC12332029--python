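"""Restraint infidelities and gradients: the finite-difference master
oracle, brute-force prefix oracles, and aggregation linearity."""

import numpy as np
import pytest

import pulseforge as pf
from pulseforge.objectives import restraint_cost

from conftest import small_mixed_spec

Z = pf.BlochVector(0, 0, 1)
MZ = pf.BlochVector(0, 0, -1)
MY = pf.BlochVector(0, -1, 0)


def _pulse(n=16, seed=0, amp_khz=17.6, dur_us=None):
    spec = pf.PulseSpec(
        nucleus="13C",
        larmor_mhz=150.9,
        carrier_ppm=58.0,
        peak_amplitude_khz=amp_khz,
        duration_us=dur_us if dur_us is not None else float(n),
        n_elements=n,
        bands=(pf.Band(40, 78, 4, pf.UniversalRotation()),),
    )
    return pf.Pulse(spec=spec, phases=pf.init_phases(n, seed))


class TestForwardPass:
    def test_single_element_definitions(self):
        pulse = _pulse(n=1)
        fp = pf.forward_pass(pulse, offset_hz=1000.0)
        v1 = pf.element_propagator(
            pf.RFElementParams(
                pulse.phases[0], pulse.spec.peak_amplitude_hz, 1000.0,
                pulse.spec.element_duration_s,
            )
        )
        np.testing.assert_allclose(fp.X[1].matrix, v1.matrix, atol=1e-13)
        expected_c = pf.dagger(v1).matrix @ pf.phase_derivative(v1)
        np.testing.assert_allclose(fp.C[0], expected_c, atol=1e-13)

    def test_total_matches_naive_product_oracle(self):
        pulse = _pulse(n=12, seed=3)
        offset, scale = -2500.0, 0.93
        fp = pf.forward_pass(pulse, offset, scale)
        acc = np.eye(2, dtype=complex)
        for phi in pulse.phases:
            v = pf.element_propagator(
                pf.RFElementParams(
                    phi, pulse.spec.peak_amplitude_hz * scale, offset,
                    pulse.spec.element_duration_s,
                )
            )
            acc = v.matrix @ acc
        np.testing.assert_allclose(fp.total.matrix, acc, atol=1e-12)
        for x in fp.X:
            assert x.is_unitary()


def _cost_for(pulse, offset, restraint, scale=1.0):
    if isinstance(restraint, pf.Suppression):
        return pf.suppression_cost(pulse, offset, scale)
    fp = pf.forward_pass(pulse, offset, scale)
    return restraint_cost(fp, restraint)


RESTRAINTS = [
    pf.UniversalRotation(axis=(0.0, 1.0, 0.0), angle=90.0),
    pf.Identity(),
    pf.StateToState("z", "-y"),
    pf.XYcite(),
    pf.Suppression(),
]


class TestGradientMasterOracle:
    @pytest.mark.parametrize("restraint", RESTRAINTS, ids=lambda r: r.name)
    def test_analytic_gradient_matches_finite_differences(self, restraint):
        pulse = _pulse(n=32, seed=7)
        offset = 1234.0
        cg = _cost_for(pulse, offset, restraint, scale=0.93)
        h = 1e-6
        fd = np.zeros(32)
        for j in range(32):
            for sgn, store in ((1, "p"), (-1, "m")):
                ph = pulse.phases.copy()
                ph[j] += sgn * h
                shifted = pf.Pulse(spec=pulse.spec, phases=ph)
                val = _cost_for(shifted, offset, restraint, scale=0.93).infidelity
                if sgn > 0:
                    plus = val
                else:
                    minus = val
            fd[j] = (plus - minus) / (2 * h)
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(cg.gradient - fd).max() / scale < 1e-6


class TestUniversalCost:
    def test_perfect_pulse_has_zero_infidelity(self):
        # one on-resonance element of duration 1/(4 nu1) is an exact 90x
        pulse = _pulse(n=1, amp_khz=25.0, dur_us=10.0)
        pulse = pf.Pulse(spec=pulse.spec, phases=np.zeros(1))
        fp = pf.forward_pass(pulse, 0.0)
        cg = pf.universal_cost(fp, pf.UniversalRotation(axis=(1.0, 0, 0), angle=90.0))
        assert cg.infidelity < 1e-12

    def test_identity_vs_180x_is_maximal(self):
        pulse = _pulse(n=1, amp_khz=0.0)
        fp = pf.forward_pass(pulse, 0.0)  # zero amplitude, zero offset: V = 1
        cg = pf.universal_cost(fp, pf.UniversalRotation(axis=(1.0, 0, 0), angle=180.0))
        assert cg.infidelity == pytest.approx(1.0)  # Tr(U^dagger) = 0

    def test_invariant_under_appending_inverse_pair(self):
        # on resonance, the inverse of an element is the same element
        # phase-shifted by pi; appending both must not change the cost
        n = 8
        base = _pulse(n=n, seed=5)
        spec2 = pf.PulseSpec(
            nucleus="13C", larmor_mhz=150.9, carrier_ppm=58.0,
            peak_amplitude_khz=base.spec.peak_amplitude_khz,
            duration_us=base.spec.duration_us * (n + 2) / n,
            n_elements=n + 2, bands=base.spec.bands,
        )
        extra = 1.234
        longer = pf.Pulse(
            spec=spec2,
            phases=np.concatenate([base.phases, [extra, extra + np.pi]]),
        )
        target = pf.UniversalRotation(axis=(0.0, 1.0, 0.0), angle=90.0)
        i1 = pf.universal_cost(pf.forward_pass(base, 0.0), target).infidelity
        i2 = pf.universal_cost(pf.forward_pass(longer, 0.0), target).infidelity
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_nonunit_axis_rejected(self):
        fp = pf.forward_pass(_pulse(n=2), 0.0)
        with pytest.raises(ValueError):
            pf.universal_cost(fp, pf.UniversalRotation(axis=(1.0, 1.0, 0.0), angle=90))


class TestS2SCost:
    def test_identity_holds_z(self):
        fp = pf.forward_pass(_pulse(n=1, amp_khz=0.0), 0.0)
        assert pf.s2s_cost(fp, Z, Z).infidelity == pytest.approx(0.0)

    def test_identity_vs_antipodal_is_one(self):
        fp = pf.forward_pass(_pulse(n=1, amp_khz=0.0), 0.0)
        assert pf.s2s_cost(fp, Z, MZ).infidelity == pytest.approx(1.0)

    def test_90x_excites_z_to_minus_y(self):
        pulse = _pulse(n=1, amp_khz=25.0, dur_us=10.0)
        pulse = pf.Pulse(spec=pulse.spec, phases=np.zeros(1))
        fp = pf.forward_pass(pulse, 0.0)
        assert pf.s2s_cost(fp, Z, MY).infidelity < 1e-12

    def test_zero_vector_rejected(self):
        fp = pf.forward_pass(_pulse(n=2), 0.0)
        with pytest.raises(ValueError):
            pf.s2s_cost(fp, pf.BlochVector(0, 0, 0), Z)


class TestXYciteCost:
    def test_identity_leaves_full_z(self):
        fp = pf.forward_pass(_pulse(n=1, amp_khz=0.0), 0.0)
        assert pf.xycite_cost(fp).infidelity == pytest.approx(1.0)

    @pytest.mark.parametrize("angle,expected", [(90.0, 0.0), (45.0, 0.5)])
    def test_flip_angle_closed_form(self, angle, expected):
        # after a rotation by theta about x, z_final = cos(theta), I = cos^2
        nu1, t90 = 25e3, 1e-5
        dur = t90 * angle / 90.0
        spec = pf.PulseSpec(
            nucleus="1H", larmor_mhz=600.0, carrier_ppm=4.77,
            peak_amplitude_khz=25.0, duration_us=dur * 1e6, n_elements=1,
            bands=(pf.Band(0, 12, 2, pf.XYcite()),),
        )
        fp = pf.forward_pass(pf.Pulse(spec=spec, phases=np.zeros(1)), 0.0)
        assert pf.xycite_cost(fp).infidelity == pytest.approx(expected, abs=1e-12)


class TestSuppressionCost:
    def test_free_evolution_holds_z_exactly(self):
        # zero-amplitude elements are pure z-rotations: every prefix holds Z
        pulse = _pulse(n=20, amp_khz=0.0, seed=2)
        cg = pf.suppression_cost(pulse, offset_hz=3000.0)
        assert cg.infidelity == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(cg.gradient, 0.0, atol=1e-12)

    def test_single_element_equals_s2s_hold(self):
        pulse = _pulse(n=1, seed=4)
        cg = pf.suppression_cost(pulse, 500.0, 1.05)
        fp = pf.forward_pass(pulse, 500.0, 1.05)
        ref = pf.s2s_cost(fp, Z, Z)
        assert cg.infidelity == pytest.approx(ref.infidelity, abs=1e-12)
        np.testing.assert_allclose(cg.gradient, ref.gradient, atol=1e-12)

    def test_matches_brute_force_prefix_oracle(self):
        pulse = _pulse(n=64, seed=9)
        offset, scale = -1700.0, 1.05
        cg = pf.suppression_cost(pulse, offset, scale)
        # oracle: mean of per-prefix Z->Z S2S costs via explicit truncation
        n = 64
        vals = []
        for k in range(1, n + 1):
            trunc_spec = pf.PulseSpec(
                nucleus="13C", larmor_mhz=150.9, carrier_ppm=58.0,
                peak_amplitude_khz=pulse.spec.peak_amplitude_khz,
                duration_us=pulse.spec.element_duration_us * k, n_elements=k,
                bands=pulse.spec.bands,
            )
            trunc = pf.Pulse(spec=trunc_spec, phases=pulse.phases[:k])
            fp = pf.forward_pass(trunc, offset, scale)
            vals.append(pf.s2s_cost(fp, Z, Z).infidelity)
        assert cg.infidelity == pytest.approx(np.mean(vals), abs=1e-12)

    def test_stride_subsampling_checks_fewer_prefixes(self):
        pulse = _pulse(n=16, seed=1)
        strided = pf.suppression_cost(pulse, 800.0, stride=4)
        # strided gradient still matches finite differences of the strided cost
        h = 1e-6
        for j in (0, 7, 15):
            ph = pulse.phases.copy()
            ph[j] += h
            ip = pf.suppression_cost(pf.Pulse(spec=pulse.spec, phases=ph), 800.0, stride=4).infidelity
            ph[j] -= 2 * h
            im = pf.suppression_cost(pf.Pulse(spec=pulse.spec, phases=ph), 800.0, stride=4).infidelity
            assert strided.gradient[j] == pytest.approx((ip - im) / (2 * h), rel=1e-5, abs=1e-10)


class TestAggregateCost:
    def test_single_condition_reduces_to_restraint_cost(self):
        spec = pf.PulseSpec(
            nucleus="15N", larmor_mhz=60.8, carrier_ppm=119.5,
            peak_amplitude_khz=6.85, duration_us=16.0, n_elements=16,
            bands=(pf.Band(110.0, 110.0, 1, pf.StateToState("z", "-y")),),
            ensemble=pf.EnsembleDistribution(points=((1.0, 1.0),)),
        )
        pulse = pf.Pulse(spec=spec, phases=pf.init_phases(16, 11))
        agg = pf.aggregate_cost(pulse)
        offset = (110.0 - 119.5) * 60.8
        ref = pf.s2s_cost(pf.forward_pass(pulse, offset), Z, MY)
        assert agg.infidelity == pytest.approx(ref.infidelity, abs=1e-12)
        np.testing.assert_allclose(agg.gradient, ref.gradient, atol=1e-12)

    def test_linear_in_ensemble_weights(self):
        spec = small_mixed_spec()
        split = pf.PulseSpec(
            **{**spec.__dict__,
               "ensemble": pf.EnsembleDistribution(
                   points=((0.93, 0.25), (1.0, 0.25), (1.0, 0.25), (1.05, 0.25))
               )},
        )
        pulse = pf.Pulse(spec=spec, phases=pf.init_phases(16, 3))
        split_pulse = pf.Pulse(spec=split, phases=pulse.phases)
        a = pf.aggregate_cost(pulse)
        b = pf.aggregate_cost(split_pulse)
        assert a.infidelity == pytest.approx(b.infidelity, abs=1e-14)
        np.testing.assert_allclose(a.gradient, b.gradient, atol=1e-14)

    def test_mixed_spec_gradient_matches_finite_differences(self):
        spec = small_mixed_spec()
        pulse = pf.Pulse(spec=spec, phases=pf.init_phases(16, 21))
        cg = pf.aggregate_cost(pulse)
        h = 1e-6
        fd = np.zeros(16)
        for j in range(16):
            ph = pulse.phases.copy()
            ph[j] += h
            ip = pf.aggregate_cost(pf.Pulse(spec=spec, phases=ph)).infidelity
            ph[j] -= 2 * h
            im = pf.aggregate_cost(pf.Pulse(spec=spec, phases=ph)).infidelity
            fd[j] = (ip - im) / (2 * h)
        assert np.abs(cg.gradient - fd).max() / np.abs(fd).max() < 1e-6

    def test_infidelity_nonnegative_for_random_pulses(self):
        spec = small_mixed_spec()
        for seed in range(10):
            pulse = pf.Pulse(spec=spec, phases=pf.init_phases(16, seed))
            assert pf.aggregate_cost(pulse).infidelity >= 0.0
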