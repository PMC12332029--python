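"""Exact spin-1/2 propagator algebra for constant-amplitude RF elements.

A single rectangular RF element applied to an isolated spin-1/2 in the
rotating frame generates the Hamiltonian (angular units of Hz)

    H = 2*pi * [ Delta * sigma_z / 2 + nu1 * (cos(phi) sigma_x + sin(phi) sigma_y) / 2 ]

where ``Delta`` is the resonance offset, ``nu1`` the RF (B1) amplitude and
``phi`` the RF phase.  Its propagator over a duration ``dt`` is the SU(2)
rotation ``exp(-i H dt)``: a rotation of the Bloch sphere about the tilted
effective field ``(nu1 cos(phi), nu1 sin(phi), Delta)`` by the angle
``2*pi*nu_eff*dt`` with ``nu_eff = sqrt(nu1**2 + Delta**2)``.

All propagators here live in the compact "scaled-unitary" (quaternion)
representation: a matrix ``[[a, -conj(b)], [b, conj(a)]]`` is stored as the
complex pair ``(a, b)``.  This set is closed under multiplication, which
halves the arithmetic of matrix products (4 complex multiplications instead
of 8) and allows the trace of a product of two such matrices to be evaluated
with exactly 4 real multiplications (see :func:`fast_trace_product`).

Sign convention: a phase-0 ("x") 90-degree pulse maps Z -> -Y, the standard
positive-gamma NMR excitation convention.  Negative-gamma nuclei (e.g. 15N)
are treated with the same effective convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SU2Propagator",
    "BlochVector",
    "RFElementParams",
    "IDENTITY",
    "element_propagator",
    "rotation_propagator",
    "compose",
    "dagger",
    "phase_derivative",
    "fast_trace_product",
    "apply_to_bloch",
]

_UNITARITY_TOL = 1e-9


@dataclass(frozen=True)
class SU2Propagator:
    """The 2x2 unitary ``[[a, -conj(b)], [b, conj(a)]]`` stored as a pair.

    ``|a|**2 + |b|**2 == 1`` for a proper rotation; scalar multiples are
    tolerated by the algebra (scaled-unitary form) but constructors of
    physical propagators always return unit pairs.
    """

    a: complex
    b: complex

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.a, -np.conj(self.b)], [self.b, np.conj(self.a)]], dtype=complex
        )

    def norm2(self) -> float:
        """|a|^2 + |b|^2 (squared quaternion norm; 1 for a unitary)."""
        return abs(self.a) ** 2 + abs(self.b) ** 2

    def is_unitary(self, tol: float = _UNITARITY_TOL) -> bool:
        return abs(self.norm2() - 1.0) < tol


IDENTITY = SU2Propagator(1.0 + 0.0j, 0.0 + 0.0j)


@dataclass(frozen=True)
class BlochVector:
    """A point on (or in) the Bloch sphere; unit norm for pure states."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def norm(self) -> float:
        return math.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass(frozen=True)
class RFElementParams:
    """One rectangular element: phase (rad), RF amplitude (Hz), offset (Hz), duration (s)."""

    phase: float
    rf_amplitude: float
    offset: float
    duration: float

    def __post_init__(self) -> None:
        vals = (self.phase, self.rf_amplitude, self.offset, self.duration)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("RF element parameters must be finite")
        if self.rf_amplitude < 0:
            raise ValueError("rf_amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def element_propagator(p: RFElementParams) -> SU2Propagator:
    """Propagator ``exp(-i H dt)`` of one constant-amplitude element.

    Uses the closed-form axis-angle expression: a rotation about the unit
    effective field ``(nu1 cos phi, nu1 sin phi, Delta)/nu_eff`` by the
    angle ``2*pi*nu_eff*dt``.
    """
    nu_eff = math.hypot(p.rf_amplitude, p.offset)
    half = math.pi * nu_eff * p.duration  # theta/2
    c, s = math.cos(half), math.sin(half)
    if nu_eff == 0.0:
        return IDENTITY
    nz = p.offset / nu_eff
    nxy = p.rf_amplitude / nu_eff
    a = complex(c, -s * nz)
    # b = s*(n_y - i n_x) = -i * s * nxy * exp(i phi)
    b = -1j * s * nxy * complex(math.cos(p.phase), math.sin(p.phase))
    return SU2Propagator(a, b)


def rotation_propagator(axis: tuple[float, float, float], angle_deg: float) -> SU2Propagator:
    """SU(2) rotation about a unit axis by an angle in degrees."""
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-8:
        raise ValueError("rotation axis must be a unit vector")
    half = math.radians(angle_deg) / 2.0
    c, s = math.cos(half), math.sin(half)
    a = complex(c, -s * ax[2])
    b = complex(s * ax[1], -s * ax[0])
    return SU2Propagator(a, b)


def compose(later: SU2Propagator, earlier: SU2Propagator) -> SU2Propagator:
    """Matrix product ``later @ earlier`` in the pair representation.

    Costs 4 complex multiplications (the naive 2x2 product costs 8); this is
    the halved multiplication scheme the scaled-unitary symmetry affords.
    """
    la, lb = later.a, later.b
    ea, eb = earlier.a, earlier.b
    return SU2Propagator(
        la * ea - lb.conjugate() * eb,
        lb * ea + la.conjugate() * eb,
    )


def dagger(v: SU2Propagator) -> SU2Propagator:
    """Adjoint: (a, b) -> (conj(a), -b)."""
    return SU2Propagator(v.a.conjugate(), -v.b)


def phase_derivative(v: SU2Propagator) -> np.ndarray:
    """Exact derivative of an element propagator w.r.t. its RF phase.

    From ``V(phi) = Rz(phi) V(0) Rz(phi)^dagger`` it follows that
    ``dV/dphi = -(i/2) (sigma_z V - V sigma_z)``, which in the pair
    representation is again quaternion-form with pair ``(0, i*b)``:

        [[0, i*conj(b)], [i*b, 0]]

    Exact at any element duration (no small-dt approximation).
    """
    ib = 1j * v.b
    return np.array([[0.0, -np.conj(ib)], [ib, 0.0]], dtype=complex)


def _fast_trace_terms(par, pai, pbr, pbi, qar, qai, qbr, qbi):
    """Tr(P Q) for two quaternion-form matrices from their real components.

    Exactly 4 multiplications:  Tr = 2*(Re(pa*qa) - Re(conj(pb)*qb)).
    Kept generic over the number type so the operation count can be audited.
    """
    m1 = par * qar
    m2 = pai * qai
    m3 = pbr * qbr
    m4 = pbi * qbi
    t = (m1 - m2) - (m3 + m4)
    return t + t  # doubling by addition keeps the multiplication count at 4


def fast_trace_product(p, q) -> complex:
    """Trace of the product of two 2x2 matrices.

    When both arguments are :class:`SU2Propagator` (compact scaled-unitary
    form) the symmetry-exploiting path with exactly 4 real multiplications
    is used and the result is purely real.  General 2x2 arrays fall back to
    the naive 4-term diagonal sum.
    """
    if isinstance(p, SU2Propagator) and isinstance(q, SU2Propagator):
        tr = _fast_trace_terms(
            p.a.real, p.a.imag, p.b.real, p.b.imag,
            q.a.real, q.a.imag, q.b.real, q.b.imag,
        )
        return complex(tr, 0.0)
    pm = p.matrix if isinstance(p, SU2Propagator) else np.asarray(p, dtype=complex)
    qm = q.matrix if isinstance(q, SU2Propagator) else np.asarray(q, dtype=complex)
    return complex(
        pm[0, 0] * qm[0, 0] + pm[0, 1] * qm[1, 0] + pm[1, 0] * qm[0, 1] + pm[1, 1] * qm[1, 1]
    )


def quaternion_components(v: SU2Propagator) -> tuple[float, float, float, float]:
    """(w, x, y, z) with V = w*I - i*(x sx + y sy + z sz)."""
    return (v.a.real, -v.b.imag, v.b.real, -v.a.imag)


def apply_to_bloch(v: SU2Propagator, n: BlochVector) -> BlochVector:
    """Bloch vector of ``V rho V^dagger`` for the pure state with vector ``n``."""
    w, x, y, z = quaternion_components(v)
    nx, ny, nz = n.x, n.y, n.z
    rx = (1 - 2 * (y * y + z * z)) * nx + 2 * (x * y - w * z) * ny + 2 * (x * z + w * y) * nz
    ry = 2 * (x * y + w * z) * nx + (1 - 2 * (x * x + z * z)) * ny + 2 * (y * z - w * x) * nz
    rz = 2 * (x * z - w * y) * nx + 2 * (y * z + w * x) * ny + (1 - 2 * (x * x + y * y)) * nz
    return BlochVector(rx, ry, rz)
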