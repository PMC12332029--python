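"""Bloch simulation of finished pulses and the machine-readable report.

The excitation profile evaluates the total propagator of a pulse over an
offset x B1-scale grid and applies it to magnetisation starting on the X,
Y and Z axes.  The default profile grid is 4x denser than the
optimization grid and offset by half a step, so that behaviour *between*
the optimization frequencies — where a too-sparse grid hides poor
performance — is always visible.

Also provides the rectangular-pulse references used for comparisons: the
on-resonance 90-degree duration 1/(4 nu1) and the null-placed durations
t90 = sqrt(15)/(4 nu), t180 = sqrt(3)/(2 nu) that put the first
excitation null at +/- nu Hz from the carrier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _engine
from .model import Band, Pulse, PulseSpec
from .optimize import OptimizationResult
from .su2 import BlochVector

__all__ = [
    "PerformanceGrid",
    "Report",
    "profile_offsets",
    "excitation_profile",
    "trajectory",
    "rectangular_t90_us",
    "null_durations_us",
    "rectangular_profile",
    "make_report",
]

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class PerformanceGrid:
    """Final Bloch vectors over offset x B1 scale x initial axis.

    ``vectors`` has shape (n_offsets, n_scales, n_axes, 3).  ``fidelity``
    (n_offsets, n_scales) holds the restraint fidelity of the band each
    offset falls in (NaN outside all bands) when a spec is available.
    """

    offsets_hz: np.ndarray
    b1_scales: np.ndarray
    initial_axes: tuple[str, ...]
    vectors: np.ndarray
    fidelity: np.ndarray | None = None

    def final(self, axis: str, scale_index: int = 0) -> np.ndarray:
        return self.vectors[:, scale_index, self.initial_axes.index(axis), :]


def profile_offsets(spec: PulseSpec, density_factor: int = 4) -> np.ndarray:
    """Offsets (Hz) for performance evaluation: per band, ``density_factor``
    times the optimization count, shifted by half a step so the evaluation
    points interleave the optimization points."""
    out = []
    for band in spec.bands:
        n = max(band.n_freqs * density_factor, 2)
        lo = (band.lo - spec.carrier_ppm) * spec.larmor_mhz
        hi = (band.hi - spec.carrier_ppm) * spec.larmor_mhz
        step = (hi - lo) / n
        out.append(np.linspace(lo + step / 2.0, hi - step / 2.0, n))
    return np.concatenate(out)


def excitation_profile(
    pulse: Pulse,
    offsets_hz: Sequence[float] | None = None,
    b1_scales: Sequence[float] | None = None,
    initial_axes: Sequence[str] = ("x", "y", "z"),
) -> PerformanceGrid:
    """Simulate the fate of magnetisation initially on each requested axis.

    Defaults: the half-step-interleaved 4x profile grid and the spec's
    ensemble scales.
    """
    spec = pulse.spec
    if offsets_hz is None:
        offsets_hz = profile_offsets(spec)
    offsets_hz = np.asarray(offsets_hz, dtype=float)
    if b1_scales is None:
        b1_scales = spec.ensemble.scales()
    b1_scales = np.asarray(b1_scales, dtype=float)
    axes = tuple(str(a).lower() for a in initial_axes)

    K, L = len(offsets_hz), len(b1_scales)
    off_flat = np.repeat(offsets_hz, L)
    nu1_flat = np.tile(b1_scales * spec.peak_amplitude_hz, K)
    xa, xb = _engine.total_propagators(
        pulse.phases, nu1_flat, off_flat, spec.element_duration_s
    )
    vectors = np.empty((K, L, len(axes), 3))
    for ai, axis in enumerate(axes):
        v = _engine.bloch_apply_pairs(xa, xb, _AXIS_VECTORS[axis])
        vectors[:, :, ai, :] = v.reshape(K, L, 3)

    fidelity = _restraint_fidelity(spec, off_flat, xa, xb).reshape(K, L)
    return PerformanceGrid(
        offsets_hz=offsets_hz,
        b1_scales=b1_scales,
        initial_axes=axes,
        vectors=vectors,
        fidelity=fidelity,
    )


def _restraint_fidelity(spec: PulseSpec, offsets, xa, xb) -> np.ndarray:
    """Per-point fidelity of the band restraint containing each offset.

    Suppression bands report the final-state Z->Z fidelity (prefix history
    is not re-evaluated on the profile grid).
    """
    from .model import Identity, StateToState, Suppression, UniversalRotation, XYcite

    fid = np.full(len(offsets), np.nan)
    for band in spec.bands:
        lo = (band.lo - spec.carrier_ppm) * spec.larmor_mhz
        hi = (band.hi - spec.carrier_ppm) * spec.larmor_mhz
        lo, hi = min(lo, hi), max(lo, hi)
        mask = (offsets >= lo - 1e-9) & (offsets <= hi + 1e-9)
        if not mask.any():
            continue
        a, b = xa[mask], xb[mask]
        r = band.restraint
        if isinstance(r, (UniversalRotation, Identity)):
            if isinstance(r, Identity):
                ua, ub = 1.0 + 0.0j, 0.0 + 0.0j
            else:
                ua, ub = _engine.rotation_pair(r.axis_vector(), r.angle)
            f = _engine.pair_trace(a, b, np.conj(ua), -ub) / 2.0
        elif isinstance(r, StateToState):
            nf = _engine.bloch_apply_pairs(a, b, np.asarray(r.start_vector()))
            f = 0.5 * (1.0 + nf @ np.asarray(r.finish_vector()))
        elif isinstance(r, XYcite):
            z = np.abs(a) ** 2 - np.abs(b) ** 2
            f = 1.0 - z * z
        elif isinstance(r, Suppression):
            z = np.abs(a) ** 2 - np.abs(b) ** 2
            f = 0.5 * (1.0 + z)
        else:  # pragma: no cover
            continue
        fid[mask] = f
    return fid


def trajectory(
    pulse: Pulse, offset_hz: float, b1_scale: float, initial: BlochVector
) -> np.ndarray:
    """Bloch vector after each prefix propagator (n+1 points incl. start)."""
    spec = pulse.spec
    Xa, Xb, _, _ = _engine.forward_scan(
        pulse.phases,
        np.array([spec.peak_amplitude_hz * b1_scale]),
        np.array([float(offset_hz)]),
        spec.element_duration_s,
    )
    return _engine.bloch_apply_pairs(Xa[:, 0], Xb[:, 0], initial.as_array())


def rectangular_t90_us(nu1_khz: float) -> float:
    """On-resonance 90-degree duration of a rectangular pulse: 1/(4 nu1)."""
    if nu1_khz <= 0:
        raise ValueError("nu1 must be > 0")
    return 1e3 / (4.0 * nu1_khz)  # 1/(4*nu1[kHz]) in ms -> us: 250/nu1_khz


def null_durations_us(nu_hz: float) -> tuple[float, float]:
    """Rectangular 90/180 durations placing the first excitation null at
    +/- nu Hz:  t90 = sqrt(15)/(4 nu),  t180 = sqrt(3)/(2 nu)."""
    if nu_hz <= 0:
        raise ValueError("nu must be > 0")
    return (math.sqrt(15.0) / (4.0 * nu_hz) * 1e6, math.sqrt(3.0) / (2.0 * nu_hz) * 1e6)


def rectangular_profile(
    nu1_hz: float,
    duration_s: float,
    offsets_hz: Sequence[float],
    initial: BlochVector = BlochVector(0.0, 0.0, 1.0),
    phase: float = 0.0,
) -> np.ndarray:
    """Final Bloch vectors of a constant-phase rectangular pulse (closed-form
    rotation about the tilted effective field)."""
    offs = np.asarray(offsets_hz, dtype=float)
    phases = np.array([phase])
    xa, xb = _engine.total_propagators(
        phases, np.full(len(offs), nu1_hz), offs, duration_s
    )
    return _engine.bloch_apply_pairs(xa, xb, initial.as_array())


@dataclass
class Report:
    """Structured performance report; the numeric payload is the source of
    truth, plots are derived artifacts.  Regenerable bit-identically from a
    stored OptimizationResult."""

    nucleus: str
    larmor_mhz: float
    carrier_ppm: float
    peak_amplitude_khz: float
    duration_us: float
    n_elements: int
    seed: int
    final_infidelity: float
    phases_rad: list[float]
    amplitude_fraction: list[float]
    infidelity_trace: list[list[float]]
    b1_scales: list[float]
    profile_offsets_hz: list[float]
    profiles: dict[str, list[list[float]]]  # axis -> (n_offsets x n_scales) z/y/x comps
    fidelity: list[list[float]]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def profile_frame(self):
        """Profile table as a pandas DataFrame (offset, scale, axis, x, y, z)."""
        import pandas as pd

        rows = []
        for ai, axis in enumerate(sorted(self.profiles)):
            arr = np.asarray(self.profiles[axis])
            for ki, off in enumerate(self.profile_offsets_hz):
                for li, sc in enumerate(self.b1_scales):
                    rows.append(
                        {
                            "offset_hz": off,
                            "b1_scale": sc,
                            "initial_axis": axis,
                            "x": arr[ki, li, 0],
                            "y": arr[ki, li, 1],
                            "z": arr[ki, li, 2],
                        }
                    )
        return pd.DataFrame(rows)


def make_report(
    result: OptimizationResult, grid: PerformanceGrid | None = None, metadata: dict | None = None
) -> Report:
    """Build the report from an optimization result (and optionally a
    pre-computed performance grid)."""
    pulse = result.pulse
    spec = pulse.spec
    if grid is None:
        grid = excitation_profile(pulse)
    profiles = {
        axis: grid.vectors[:, :, ai, :].tolist()
        for ai, axis in enumerate(grid.initial_axes)
    }
    return Report(
        nucleus=spec.nucleus,
        larmor_mhz=spec.larmor_mhz,
        carrier_ppm=spec.carrier_ppm,
        peak_amplitude_khz=spec.peak_amplitude_khz,
        duration_us=spec.duration_us,
        n_elements=spec.n_elements,
        seed=result.seed,
        final_infidelity=result.infidelity,
        phases_rad=list(map(float, pulse.phases)),
        amplitude_fraction=[1.0] * spec.n_elements,
        infidelity_trace=[[float(i), float(v)] for i, v in result.trace],
        b1_scales=list(map(float, grid.b1_scales)),
        profile_offsets_hz=list(map(float, grid.offsets_hz)),
        profiles=profiles,
        fidelity=np.asarray(grid.fidelity).tolist(),
        metadata=metadata or {},
    )


def b1_fidelity_gap(grid: PerformanceGrid) -> float:
    """Max pairwise gap between the fidelity curves at the different B1
    scales — small for a well-compensated pulse."""
    f = np.asarray(grid.fidelity)
    gaps = [
        np.nanmax(np.abs(f[:, i] - f[:, j]))
        for i in range(f.shape[1])
        for j in range(i + 1, f.shape[1])
    ]
    return float(max(gaps)) if gaps else 0.0


def plot_report(report: Report, path: str) -> None:
    """Render phase waveform, convergence and X/Y/Z-fate profiles to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axes_names = sorted(report.profiles)
    fig, axs = plt.subplots(2 + len(axes_names), 1, figsize=(7, 10))
    axs[0].step(range(report.n_elements), np.degrees(report.phases_rad), where="mid")
    axs[0].set_ylabel("phase (deg)")
    axs[0].set_xlabel("element")
    tr = np.asarray(report.infidelity_trace)
    if len(tr):
        axs[1].semilogy(tr[:, 0], np.maximum(tr[:, 1], 1e-16))
    axs[1].set_ylabel("infidelity")
    axs[1].set_xlabel("iteration")
    offs = np.asarray(report.profile_offsets_hz)
    for k, axis in enumerate(axes_names):
        arr = np.asarray(report.profiles[axis])
        for li, sc in enumerate(report.b1_scales):
            axs[2 + k].plot(offs, arr[:, li, 2], label=f"B1 x{sc:g}")
        axs[2 + k].set_ylabel(f"Mz from {axis.upper()}")
        axs[2 + k].set_xlabel("offset (Hz)")
        axs[2 + k].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
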