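"""Vectorized numerical core: batched propagator scans and cost/gradient kernels.

Everything here works on flat numpy arrays.  A "condition" is one
(offset, B1-scale) pair; the scan is sequential over elements but fully
vectorized over conditions, so a cost/gradient evaluation for the whole
frequency x ensemble grid costs one n-step loop of short vector operations.

Pair representation throughout: a quaternion-form 2x2 matrix
``[[a, -conj(b)], [b, conj(a)]]`` is the complex pair (a, b).  The phase
derivative of an element propagator is again quaternion-form with pair
(0, i*b), so every partial product and derivative kernel stays compact.
"""

from __future__ import annotations

import numpy as np

from .model import (
    Band,
    Identity,
    PulseSpec,
    Restraint,
    StateToState,
    Suppression,
    UniversalRotation,
    XYcite,
    band_grid,
)

_SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)


def element_pairs(phases: np.ndarray, nu1: np.ndarray, offsets: np.ndarray, dt: float):
    """Per-condition constants (a0, b0) such that element j has pair
    (a0, b0 * exp(i*phi_j)).

    The effective-field tilt depends only on the condition, not on the
    phase, so a0 is phase-independent and b0 carries only the transverse
    magnitude.
    """
    veff = np.hypot(nu1, offsets)
    half = np.pi * veff * dt
    c, s = np.cos(half), np.sin(half)
    safe = np.where(veff > 0, veff, 1.0)
    nz = np.where(veff > 0, offsets / safe, 0.0)
    nxy = np.where(veff > 0, nu1 / safe, 0.0)
    a0 = c - 1j * s * nz
    b0 = -1j * s * nxy
    return a0, b0


def forward_scan(phases: np.ndarray, nu1: np.ndarray, offsets: np.ndarray, dt: float):
    """Partial products and derivative kernels for every condition.

    Returns (Xa, Xb, Ca, Cb): X arrays of shape (n+1, m) with X[0] the
    identity, C arrays of shape (n, m) holding the pair of
    ``C_j = X_j^dagger (dV_j/dphi_j) X_{j-1}``.
    """
    phases = np.asarray(phases, dtype=float)
    nu1 = np.atleast_1d(np.asarray(nu1, dtype=float))
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    n = phases.shape[0]
    m = offsets.shape[0]
    a0, b0 = element_pairs(phases, nu1, offsets, dt)
    eiphi = np.exp(1j * phases)

    Xa = np.empty((n + 1, m), dtype=complex)
    Xb = np.empty((n + 1, m), dtype=complex)
    Xa[0] = 1.0
    Xb[0] = 0.0
    a0c = np.conj(a0)
    for j in range(n):
        bj = b0 * eiphi[j]
        xa, xb = Xa[j], Xb[j]
        Xa[j + 1] = a0 * xa - np.conj(bj) * xb
        Xb[j + 1] = bj * xa + a0c * xb

    # Derivative kernels, vectorized over (element, condition).
    bj_all = b0[None, :] * eiphi[:, None]          # (n, m)
    Ta = 1j * bj_all * np.conj(Xb[1:])             # X_j includes element j
    Tb = 1j * bj_all * Xa[1:]
    Ca = Ta * Xa[:-1] - np.conj(Tb) * Xb[:-1]
    Cb = Tb * Xa[:-1] + np.conj(Ta) * Xb[:-1]
    return Xa, Xb, Ca, Cb


def bloch_apply_pairs(a: np.ndarray, b: np.ndarray, n0: np.ndarray) -> np.ndarray:
    """Rotate Bloch vector(s) n0 (3,) by the pair propagators; returns (..., 3)."""
    w, x, y, z = a.real, -b.imag, b.real, -a.imag
    nx, ny, nz = n0
    rx = (1 - 2 * (y * y + z * z)) * nx + 2 * (x * y - w * z) * ny + 2 * (x * z + w * y) * nz
    ry = 2 * (x * y + w * z) * nx + (1 - 2 * (x * x + z * z)) * ny + 2 * (y * z - w * x) * nz
    rz = 2 * (x * z - w * y) * nx + 2 * (y * z + w * x) * ny + (1 - 2 * (x * x + y * y)) * nz
    return np.stack([rx, ry, rz], axis=-1)


def pair_trace(pa, pb, qa, qb):
    """Tr(PQ) for quaternion-form pairs (real-valued, returned as float array)."""
    return 2.0 * ((pa * qa).real - (np.conj(pb) * qb).real)


def _pair_mul(pa, pb, qa, qb):
    """Pair of the product P@Q of two quaternion-form matrices."""
    return pa * qa - np.conj(pb) * qb, pb * qa + np.conj(pa) * qb


def rotation_pair(axis, angle_deg: float):
    ax = np.asarray(axis, dtype=float)
    half = np.radians(angle_deg) / 2.0
    c, s = np.cos(half), np.sin(half)
    return complex(c, -s * ax[2]), complex(s * ax[1], -s * ax[0])


def _density(nvec) -> np.ndarray:
    nx, ny, nz = nvec
    return 0.5 * np.array(
        [[1 + nz, nx - 1j * ny], [nx + 1j * ny, 1 - nz]], dtype=complex
    )


def universal_kernel(Xa, Xb, Ca, Cb, ua, ub, phase_sensitive=True):
    """Infidelity and gradient per condition for a universal-rotation target.

    F = Tr(V U^dagger)/2 (real for quaternion-form matrices); I = 1 - F.
    Gradient: dI/dphi_j = Re Tr(B C_j) with B = -(U^dagger/2) V.
    The phase-insensitive variant uses F = (Tr(V U^dagger)/2)^2.
    """
    Va, Vb = Xa[-1], Xb[-1]
    uda, udb = np.conj(ua), -ub  # U^dagger pair
    T = pair_trace(Va, Vb, uda, udb)  # (m,) real: Tr(V U^dagger)... note order
    # pair_trace(P,Q)=Tr(PQ); we need Tr(V U^dagger): P=V, Q=U^dagger.
    F = T / 2.0
    Ba, Bb = _pair_mul(uda / 2.0, udb / 2.0, Va, Vb)  # W V with W=U^dagger/2
    g = -pair_trace(Ba[None, :], Bb[None, :], Ca, Cb)  # -(dF/dphi_j)
    if phase_sensitive:
        infid = 1.0 - F
        grad = g
    else:
        infid = 1.0 - F * F
        grad = 2.0 * F[None, :] * g
    return infid, grad


def _general_trace_with_pair(M, Ca, Cb):
    """Re Tr(M C_j) for general per-condition 2x2 M (m,2,2) and pair C (n,m)."""
    t = (
        M[None, :, 0, 0] * Ca
        + M[None, :, 0, 1] * Cb
        - M[None, :, 1, 0] * np.conj(Cb)
        + M[None, :, 1, 1] * np.conj(Ca)
    )
    return t.real


def _v_matrices(Va, Vb) -> np.ndarray:
    m = Va.shape[0]
    V = np.empty((m, 2, 2), dtype=complex)
    V[:, 0, 0] = Va
    V[:, 0, 1] = -np.conj(Vb)
    V[:, 1, 0] = Vb
    V[:, 1, 1] = np.conj(Va)
    return V


def s2s_kernel(Xa, Xb, Ca, Cb, start, finish):
    """State-to-state infidelity per condition.

    F = (1 + n_final . n_finish)/2 with n_final the rotated start vector;
    dI/dphi_j = -2 Re Tr((rho_s V^dagger rho_f V) C_j).
    """
    Va, Vb = Xa[-1], Xb[-1]
    nfinal = bloch_apply_pairs(Va, Vb, np.asarray(start, dtype=float))
    F = 0.5 * (1.0 + nfinal @ np.asarray(finish, dtype=float))
    V = _v_matrices(Va, Vb)
    Vd = np.conj(np.swapaxes(V, -1, -2))
    rs = _density(start)
    rf = _density(finish)
    M = np.einsum("ab,mbc,cd,mde->mae", rs, Vd, rf, V)
    grad = -2.0 * _general_trace_with_pair(M, Ca, Cb)
    return 1.0 - F, grad


def xycite_kernel(Xa, Xb, Ca, Cb):
    """XYcite: I = z_final^2 for a spin starting on +Z.

    dI/dphi_j = 2 z Re Tr((sigma_z V^dagger sigma_z V) C_j).
    """
    Va, Vb = Xa[-1], Xb[-1]
    z = np.abs(Va) ** 2 - np.abs(Vb) ** 2
    V = _v_matrices(Va, Vb)
    Vd = np.conj(np.swapaxes(V, -1, -2))
    M = np.einsum("ab,mbc,cd,mde->mae", _SIGMA_Z, Vd, _SIGMA_Z, V)
    grad = 2.0 * z[None, :] * _general_trace_with_pair(M, Ca, Cb)
    return z * z, grad


def suppression_kernel(Xa, Xb, Ca, Cb):
    """Prefix-hold (Z->Z at every element) infidelity per condition.

    I = 1 - (1/n) sum_k F_k with F_k the Z->Z fidelity of prefix X_k.
    The gradient double sum over (j, k>=j) collapses to a single pass via
    suffix accumulation of the per-prefix kernels B_k, since the trace is
    linear: dI/dphi_j = Re Tr((sum_{k>=j} B_k) C_j).
    """
    n = Ca.shape[0]
    pa, pb = Xa[1:], Xb[1:]  # prefixes X_1..X_n, shape (n, m)
    zk = np.abs(pa) ** 2 - np.abs(pb) ** 2
    infid = 1.0 - np.mean(0.5 * (1.0 + zk), axis=0)
    # B_k = -(2/n) rho_z X_k^dagger rho_z X_k; only the first row is nonzero:
    #   B_k[0,0] = -(2/n)|a_k|^2,  B_k[0,1] = (2/n) conj(a_k) conj(b_k)
    B00 = -(2.0 / n) * (np.abs(pa) ** 2)
    B01 = (2.0 / n) * np.conj(pa) * np.conj(pb)
    S00 = np.cumsum(B00[::-1], axis=0)[::-1]  # suffix sums over k >= j
    S01 = np.cumsum(B01[::-1], axis=0)[::-1]
    grad = (S00 * Ca + S01 * Cb).real
    return infid, grad


def band_kernel(restraint: Restraint):
    """Dispatch a restraint to its (infidelity, gradient) kernel."""
    if isinstance(restraint, (UniversalRotation, Identity)):
        if isinstance(restraint, Identity):
            ua, ub = 1.0 + 0.0j, 0.0 + 0.0j
        else:
            ua, ub = rotation_pair(restraint.axis_vector(), restraint.angle)
        return lambda Xa, Xb, Ca, Cb: universal_kernel(Xa, Xb, Ca, Cb, ua, ub)
    if isinstance(restraint, StateToState):
        s, f = restraint.start_vector(), restraint.finish_vector()
        return lambda Xa, Xb, Ca, Cb: s2s_kernel(Xa, Xb, Ca, Cb, s, f)
    if isinstance(restraint, XYcite):
        return xycite_kernel
    if isinstance(restraint, Suppression):
        return suppression_kernel
    raise TypeError(f"unknown restraint: {restraint!r}")


def spec_conditions(spec: PulseSpec):
    """Flatten (ensemble point x band x frequency) into condition arrays.

    Returns (offsets, nu1, weights, groups) where groups is a list of
    (slice, kernel) pairs covering the condition axis.  Weights are
    ensemble weight / total frequency count: a band's influence scales
    with its frequency count by design (no per-band renormalization).
    """
    n_total = spec.total_frequencies
    offsets_l, nu1_l, w_l, groups = [], [], [], []
    pos = 0
    for scale, wgt in spec.ensemble.points:
        for band in spec.bands:
            offs = band_grid(band, spec.carrier_ppm, spec.larmor_mhz)
            k = len(offs)
            offsets_l.append(offs)
            nu1_l.append(np.full(k, spec.peak_amplitude_hz * scale))
            w_l.append(np.full(k, wgt / n_total))
            groups.append((slice(pos, pos + k), band_kernel(band.restraint)))
            pos += k
    return (
        np.concatenate(offsets_l),
        np.concatenate(nu1_l),
        np.concatenate(w_l),
        groups,
    )


def aggregate_cost_grad(phases: np.ndarray, spec: PulseSpec):
    """Ensemble- and band-averaged infidelity and its exact gradient."""
    offsets, nu1, weights, groups = spec_conditions(spec)
    dt = spec.element_duration_s
    Xa, Xb, Ca, Cb = forward_scan(phases, nu1, offsets, dt)
    total = 0.0
    grad = np.zeros(len(phases))
    for sl, kernel in groups:
        infid, g = kernel(Xa[:, sl], Xb[:, sl], Ca[:, sl], Cb[:, sl])
        w = weights[sl]
        total += float(infid @ w)
        grad += g @ w
    return total, grad


def total_propagators(phases, nu1, offsets, dt):
    """Final propagator pair only (no prefix storage) for profile simulation."""
    phases = np.asarray(phases, dtype=float)
    nu1 = np.atleast_1d(np.asarray(nu1, dtype=float))
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    a0, b0 = element_pairs(phases, nu1, offsets, dt)
    eiphi = np.exp(1j * phases)
    xa = np.ones_like(a0)
    xb = np.zeros_like(a0)
    a0c = np.conj(a0)
    for j in range(phases.shape[0]):
        bj = b0 * eiphi[j]
        xa, xb = a0 * xa - np.conj(bj) * xb, bj * xa + a0c * xb
    return xa, xb
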