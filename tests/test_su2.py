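"""Propagator algebra: closed forms against independent matrix oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import pulseforge as pf
from pulseforge.su2 import IDENTITY, _fast_trace_terms

from conftest import random_element, random_su2

unit_quaternions = st.lists(
    st.floats(-1.0, 1.0), min_size=4, max_size=4
).filter(lambda v: np.linalg.norm(v) > 1e-3).map(
    lambda v: (np.asarray(v) / np.linalg.norm(v)).tolist()
)


def _su2(q):
    return pf.SU2Propagator(complex(q[0], q[1]), complex(q[2], q[3]))

SX = np.array([[0, 1], [1, 0]], dtype=complex)
SY = np.array([[0, -1j], [1j, 0]], dtype=complex)
SZ = np.array([[1, 0], [0, -1]], dtype=complex)


def hamiltonian(p: pf.RFElementParams) -> np.ndarray:
    return 2 * np.pi * (
        p.offset * SZ / 2
        + p.rf_amplitude * (np.cos(p.phase) * SX + np.sin(p.phase) * SY) / 2
    )


class TestElementPropagator:
    def test_zero_hamiltonian_is_identity(self):
        v = pf.element_propagator(pf.RFElementParams(0.0, 0.0, 0.0, 10e-6))
        assert v.a == 1.0 and v.b == 0.0

    def test_quarter_period_90x_excites_z_to_minus_y(self):
        # dt = 1/(4 nu1) forces a 90-degree rotation about +x
        v = pf.element_propagator(pf.RFElementParams(0.0, 25e3, 0.0, 1e-5))
        n = pf.apply_to_bloch(v, pf.BlochVector(0, 0, 1))
        np.testing.assert_allclose([n.x, n.y, n.z], [0, -1, 0], atol=1e-12)

    def test_matches_matrix_exponential_oracle(self, rng):
        # 1000 random parameter draws against an independent expm oracle
        worst = 0.0
        for _ in range(1000):
            p = random_element(rng)
            v = pf.element_propagator(p).matrix
            ref = expm(-1j * hamiltonian(p) * p.duration)
            worst = max(worst, np.abs(v - ref).max())
        assert worst < 1e-11

    def test_rejects_nonfinite_and_invalid(self):
        with pytest.raises(ValueError):
            pf.RFElementParams(np.nan, 1e3, 0.0, 1e-6)
        with pytest.raises(ValueError):
            pf.RFElementParams(0.0, -1.0, 0.0, 1e-6)
        with pytest.raises(ValueError):
            pf.RFElementParams(0.0, 1e3, 0.0, 0.0)


class TestCompose:
    def test_identity_neutral(self, rng):
        v = random_su2(rng)
        w = pf.compose(IDENTITY, v)
        assert w.a == pytest.approx(v.a) and w.b == pytest.approx(v.b)

    def test_inverse_gives_identity(self, rng):
        v = random_su2(rng)
        w = pf.compose(v, pf.dagger(v))
        assert abs(w.a - 1) < 1e-12 and abs(w.b) < 1e-12

    def test_matches_naive_matmul_oracle(self, rng):
        for _ in range(200):
            p, q = random_su2(rng), random_su2(rng)
            np.testing.assert_allclose(
                pf.compose(p, q).matrix, p.matrix @ q.matrix, atol=1e-13
            )

    @settings(max_examples=100, derandomize=True)
    @given(p=unit_quaternions, q=unit_quaternions, r=unit_quaternions)
    def test_composition_associative_and_unitary(self, p, q, r):
        a, b, c = _su2(p), _su2(q), _su2(r)
        left = pf.compose(pf.compose(a, b), c)
        right = pf.compose(a, pf.compose(b, c))
        np.testing.assert_allclose(left.matrix, right.matrix, atol=1e-12)
        assert abs(left.norm2() - 1.0) < 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(q=unit_quaternions, n=unit_quaternions)
    def test_bloch_rotation_preserves_norm_and_angles(self, q, n):
        v = _su2(q)
        vec = pf.BlochVector(n[0], n[1], n[2] + 0.0)
        scale = vec.norm()
        out = pf.apply_to_bloch(v, vec)
        assert out.norm() == pytest.approx(scale, abs=1e-12)

    def test_unitarity_drift_over_1e4_compositions(self, rng):
        acc = IDENTITY
        for _ in range(10_000):
            acc = pf.compose(random_su2(rng), acc)
        assert abs(acc.norm2() - 1.0) < 1e-10


class TestPhaseDerivative:
    def test_identity_commutes(self):
        assert np.abs(pf.phase_derivative(IDENTITY)).max() == 0.0

    def test_pure_z_rotation_commutes(self):
        v = pf.element_propagator(pf.RFElementParams(0.3, 0.0, 5e3, 4e-6))
        assert np.abs(pf.phase_derivative(v)).max() < 1e-15

    @pytest.mark.parametrize("case", ["x90", "random"])
    def test_matches_finite_differences(self, case, rng):
        h = 1e-6
        n_draws = 1 if case == "x90" else 100
        for _ in range(n_draws):
            if case == "x90":
                p = pf.RFElementParams(0.0, 25e3, 0.0, 1e-5)
            else:
                p = random_element(rng)
            d = pf.phase_derivative(pf.element_propagator(p))
            plus = pf.element_propagator(
                pf.RFElementParams(p.phase + h, p.rf_amplitude, p.offset, p.duration)
            ).matrix
            minus = pf.element_propagator(
                pf.RFElementParams(p.phase - h, p.rf_amplitude, p.offset, p.duration)
            ).matrix
            fd = (plus - minus) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-30)
            assert np.abs(d - fd).max() / scale < 1e-6


class TestFastTraceProduct:
    def test_identity_trace(self):
        assert pf.fast_trace_product(IDENTITY, IDENTITY) == 2.0 + 0j

    def test_matches_naive_trace(self, rng):
        for _ in range(1000):
            p, q = random_su2(rng), random_su2(rng)
            naive = np.trace(p.matrix @ q.matrix)
            assert abs(pf.fast_trace_product(p, q) - naive) < 1e-12

    def test_fast_path_uses_exactly_four_multiplications(self):
        class Counted(float):
            count = [0]

            def __mul__(self, other):
                Counted.count[0] += 1
                return Counted(float(self) * float(other))

            __rmul__ = __mul__

            def __add__(self, other):
                return Counted(float(self) + float(other))

            def __sub__(self, other):
                return Counted(float(self) - float(other))

        Counted.count[0] = 0
        args = [Counted(v) for v in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)]
        _fast_trace_terms(*args)
        assert Counted.count[0] == 4


class TestApplyToBloch:
    def test_identity_preserves(self):
        n = pf.apply_to_bloch(IDENTITY, pf.BlochVector(0.6, 0.0, 0.8))
        assert (n.x, n.y, n.z) == (0.6, 0.0, 0.8)

    def test_matches_density_matrix_conjugation_oracle(self, rng):
        for _ in range(200):
            v = random_su2(rng)
            raw = rng.normal(size=3)
            raw /= np.linalg.norm(raw)
            n = pf.BlochVector(*raw)
            got = pf.apply_to_bloch(v, n)
            rho = 0.5 * (np.eye(2) + raw[0] * SX + raw[1] * SY + raw[2] * SZ)
            rho2 = v.matrix @ rho @ v.matrix.conj().T
            ref = [np.trace(rho2 @ s).real for s in (SX, SY, SZ)]
            np.testing.assert_allclose([got.x, got.y, got.z], ref, atol=1e-12)
            assert abs(got.norm() - 1.0) < 1e-12
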