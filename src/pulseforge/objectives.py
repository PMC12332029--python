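"""The four restraint infidelity functionals and their exact phase gradients.

Every restraint is written in a common trace framework.  With the pulse
propagator ``V = V_n ... V_1``, the partial products ``X_j = V_j X_{j-1}``
and the derivative kernels ``C_j = X_j^dagger (dV_j/dphi_j) X_{j-1}``, the
phase derivative of the propagator is ``dV/dphi_j = V C_j``, so every
gradient reduces to ``Re Tr(B C_j)`` for a restraint-specific matrix B.

Normalizations are fixed so that I = 0 exactly at perfection:

* universal/identity:  F = Re Tr(V U^dagger)/2,  I = 1 - F
* state-to-state:      F = (1 + n_final . n_finish)/2,  I = 1 - F
* XYcite:              I = z_final^2  (spin starting on +Z)
* suppression:         I = 1 - mean_k F_k  over the Z->Z fidelities of all
  prefix propagators X_k

and all gradients are validated against central finite differences.

The ensemble/band aggregate averages *infidelities* with the B1 weights.
Conditions (frequency x B1 scale) are mutually independent, so the
evaluation is embarrassingly parallel; here it is vectorized over all
conditions in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .model import (
    Identity,
    Pulse,
    PulseSpec,
    Restraint,
    StateToState,
    UniversalRotation,
)
from .su2 import BlochVector, SU2Propagator

__all__ = [
    "ForwardPass",
    "CostGrad",
    "forward_pass",
    "universal_cost",
    "s2s_cost",
    "xycite_cost",
    "suppression_cost",
    "aggregate_cost",
]


@dataclass
class ForwardPass:
    """Partial products X_0..X_n and derivative kernels C_1..C_n for one
    (offset, B1-scale) condition, stored compactly as complex pairs."""

    Xa: np.ndarray  # (n+1,)
    Xb: np.ndarray
    Ca: np.ndarray  # (n,)
    Cb: np.ndarray

    @property
    def n(self) -> int:
        return len(self.Ca)

    @property
    def X(self) -> list[SU2Propagator]:
        return [SU2Propagator(complex(a), complex(b)) for a, b in zip(self.Xa, self.Xb)]

    @property
    def C(self) -> list[np.ndarray]:
        """Derivative kernels as explicit 2x2 matrices."""
        return [
            np.array([[ca, -np.conj(cb)], [cb, np.conj(ca)]], dtype=complex)
            for ca, cb in zip(self.Ca, self.Cb)
        ]

    @property
    def total(self) -> SU2Propagator:
        return SU2Propagator(complex(self.Xa[-1]), complex(self.Xb[-1]))


@dataclass
class CostGrad:
    """An infidelity value with its gradient over element phases (per rad)."""

    infidelity: float
    gradient: np.ndarray


def forward_pass(pulse: Pulse, offset_hz: float, b1_scale: float = 1.0) -> ForwardPass:
    """Run the element scan for one condition; each element's amplitude is
    the spec peak amplitude times ``b1_scale``."""
    spec = pulse.spec
    Xa, Xb, Ca, Cb = _engine.forward_scan(
        pulse.phases,
        np.array([spec.peak_amplitude_hz * b1_scale]),
        np.array([float(offset_hz)]),
        spec.element_duration_s,
    )
    return ForwardPass(Xa[:, 0], Xb[:, 0], Ca[:, 0], Cb[:, 0])


def _as_batch(fp: ForwardPass):
    return (
        fp.Xa[:, None],
        fp.Xb[:, None],
        fp.Ca[:, None],
        fp.Cb[:, None],
    )


def universal_cost(
    fp: ForwardPass, target: Restraint, phase_sensitive: bool = True
) -> CostGrad:
    """Universal-rotation (or identity) infidelity for one condition.

    The default fidelity Re Tr(V U^dagger)/2 is phase-sensitive
    (distinguishes U from -U); ``phase_sensitive=False`` uses
    (Tr(V U^dagger)/2)^2, indifferent to the physically irrelevant
    2*pi-rotation sign.
    """
    if isinstance(target, Identity):
        ua, ub = 1.0 + 0.0j, 0.0 + 0.0j
    elif isinstance(target, UniversalRotation):
        ax = np.asarray(target.axis_vector(), dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-8:
            raise ValueError("universal rotation axis must be unit norm")
        ua, ub = _engine.rotation_pair(ax, target.angle)
    else:
        raise TypeError("target must be UniversalRotation or Identity")
    infid, grad = _engine.universal_kernel(*_as_batch(fp), ua, ub, phase_sensitive)
    return CostGrad(float(infid[0]), grad[:, 0])


def s2s_cost(fp: ForwardPass, start: BlochVector, finish: BlochVector) -> CostGrad:
    """State-to-state infidelity I = (1 - n_final . n_finish)/2 in [0, 1]."""
    for v in (start, finish):
        if abs(v.norm() - 1.0) > 1e-8:
            raise ValueError("start/finish must be unit Bloch vectors")
    infid, grad = _engine.s2s_kernel(
        *_as_batch(fp), start.as_array(), finish.as_array()
    )
    return CostGrad(float(infid[0]), grad[:, 0])


def xycite_cost(fp: ForwardPass) -> CostGrad:
    """Select against a residual Z component: I = z_final^2 (start state +Z)."""
    infid, grad = _engine.xycite_kernel(*_as_batch(fp))
    return CostGrad(float(infid[0]), grad[:, 0])


def suppression_cost(
    pulse: Pulse, offset_hz: float, b1_scale: float = 1.0, stride: int = 1
) -> CostGrad:
    """Prefix-hold infidelity: mean Z->Z infidelity over every prefix.

    ``stride`` subsamples the checkpoints (every stride-th element plus the
    final one) to cut the cost of this relatively demanding restraint;
    the default checks every element.
    """
    fp = forward_pass(pulse, offset_hz, b1_scale)
    if stride == 1:
        infid, grad = _engine.suppression_kernel(*_as_batch(fp))
        return CostGrad(float(infid[0]), grad[:, 0])
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = fp.n
    keep = sorted(set(range(stride - 1, n, stride)) | {n - 1})  # element indices
    pa, pb = fp.Xa[1:][keep], fp.Xb[1:][keep]
    zk = np.abs(pa) ** 2 - np.abs(pb) ** 2
    infid = 1.0 - float(np.mean(0.5 * (1.0 + zk)))
    nk = len(keep)
    B00 = -(2.0 / nk) * np.abs(pa) ** 2
    B01 = (2.0 / nk) * np.conj(pa) * np.conj(pb)
    grad = np.zeros(n)
    for j in range(n):
        mask = [i for i, k in enumerate(keep) if k >= j]
        s00 = B00[mask].sum()
        s01 = B01[mask].sum()
        grad[j] = (s00 * fp.Ca[j] + s01 * fp.Cb[j]).real
    return CostGrad(infid, grad)


def aggregate_cost(pulse: Pulse, spec: PulseSpec | None = None) -> CostGrad:
    """Total infidelity over all bands, frequencies and ensemble points.

    I_total = sum_e w_e * sum_bands sum_freqs I(band, freq, e) / N_freqs,
    with N_freqs the total frequency count over all bands; a band's
    influence therefore grows with its frequency count.
    """
    spec = spec if spec is not None else pulse.spec
    total, grad = _engine.aggregate_cost_grad(pulse.phases, spec)
    return CostGrad(total, grad)


def restraint_cost(fp: ForwardPass, restraint: Restraint, pulse_ctx=None) -> CostGrad:
    """Evaluate any restraint for a single condition (dispatch helper)."""
    kernel = _engine.band_kernel(restraint)
    infid, grad = kernel(*_as_batch(fp))
    return CostGrad(float(infid[0]), grad[:, 0])
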