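"""Declarative description of a pulse-design problem.

A :class:`PulseSpec` bundles everything needed to design one shaped pulse:
the nucleus and its Larmor frequency, the carrier position, the fixed peak
RF amplitude and total duration, the number of rectangular elements, one or
more chemical-shift *bands* (each with its own restraint and frequency
count), and the B1-amplitude ensemble over which the infidelity is
averaged.

User-facing units are the spectroscopist's (kHz, us, ppm, MHz, degrees);
the numerical engine works in Hz / seconds / radians, converted at this
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Restraint",
    "UniversalRotation",
    "Identity",
    "StateToState",
    "XYcite",
    "Suppression",
    "Band",
    "EnsembleDistribution",
    "PulseSpec",
    "Pulse",
    "SpecValidationError",
    "cardinal_vector",
    "ppm_to_offset_hz",
    "band_grid",
    "default_ensemble",
    "validate_spec",
]

_CARDINALS = {
    "x": (1.0, 0.0, 0.0),
    "y": (0.0, 1.0, 0.0),
    "z": (0.0, 0.0, 1.0),
}


def cardinal_vector(label: str) -> tuple[float, float, float]:
    """Map a cardinal label ('+z', '-y', 'x', ...) to a unit vector."""
    s = label.strip().lower()
    sign = 1.0
    if s and s[0] in "+-":
        sign = -1.0 if s[0] == "-" else 1.0
        s = s[1:]
    if s not in _CARDINALS:
        raise ValueError(f"not a cardinal axis label: {label!r}")
    vx, vy, vz = _CARDINALS[s]
    return (sign * vx, sign * vy, sign * vz)


class Restraint:
    """Base class for the four band restraints."""

    name = "restraint"


@dataclass(frozen=True)
class UniversalRotation(Restraint):
    """Target rotation of the whole Bloch sphere (3-axis control).

    ``axis`` is a unit vector (or cardinal label) and ``angle`` is in
    degrees.  The identity restraint is the special case angle=0.
    """

    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    angle: float = 90.0
    name = "universal"

    def axis_vector(self) -> tuple[float, float, float]:
        ax = self.axis
        if isinstance(ax, str):
            return cardinal_vector(ax)
        return tuple(float(c) for c in ax)  # type: ignore[return-value]


@dataclass(frozen=True)
class Identity(Restraint):
    """Universal rotation whose target is the identity: the pulse undoes its
    own chemical-shift evolution ("zero-time" behaviour)."""

    name = "identity"


@dataclass(frozen=True)
class StateToState(Restraint):
    """Map one cardinal state to another (1 axis of control), e.g. Z -> -Y."""

    start: str = "z"
    finish: str = "-y"
    name = "s2s"

    def start_vector(self) -> tuple[float, float, float]:
        return cardinal_vector(self.start)

    def finish_vector(self) -> tuple[float, float, float]:
        return cardinal_vector(self.finish)


@dataclass(frozen=True)
class XYcite(Restraint):
    """Select against any residual Z component at the end of the pulse; the
    final transverse phase is unconstrained."""

    name = "xycite"


@dataclass(frozen=True)
class Suppression(Restraint):
    """Hold the spin on +Z at every intermediate element of the pulse
    (prefix-wise Z -> Z), used for solvent suppression."""

    name = "suppression"


@dataclass(frozen=True)
class Band:
    """A ppm interval with its optimization frequency count and restraint."""

    lo: float
    hi: float
    n_freqs: int
    restraint: Restraint


@dataclass(frozen=True)
class EnsembleDistribution:
    """B1 amplitude distribution: (scale, weight) pairs.

    Scales multiply the peak amplitude; weights must sum to 1.
    """

    points: tuple[tuple[float, float], ...]

    def scales(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    def weights(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


def default_ensemble() -> EnsembleDistribution:
    """Three-point B1 distribution at 0.93/1.00/1.05 of the nominal field,
    weighted 1/4, 1/2, 1/4 — the compensation scheme used throughout."""
    return EnsembleDistribution(points=((0.93, 0.25), (1.00, 0.50), (1.05, 0.25)))


@dataclass(frozen=True)
class PulseSpec:
    """The full design problem for one shaped pulse."""

    nucleus: str
    larmor_mhz: float
    carrier_ppm: float
    peak_amplitude_khz: float
    duration_us: float
    n_elements: int
    bands: tuple[Band, ...]
    ensemble: EnsembleDistribution = field(default_factory=default_ensemble)

    @property
    def element_duration_us(self) -> float:
        return self.duration_us / self.n_elements

    @property
    def element_duration_s(self) -> float:
        return self.duration_us * 1e-6 / self.n_elements

    @property
    def peak_amplitude_hz(self) -> float:
        return self.peak_amplitude_khz * 1e3

    @property
    def total_frequencies(self) -> int:
        return sum(b.n_freqs for b in self.bands)


@dataclass(frozen=True)
class Pulse:
    """A constant-amplitude, phase-only pulse: the spec plus its phases (rad)."""

    spec: PulseSpec
    phases: np.ndarray

    def __post_init__(self) -> None:
        ph = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", ph)
        if ph.shape != (self.spec.n_elements,):
            raise ValueError(
                f"phases has length {ph.shape}, spec declares {self.spec.n_elements} elements"
            )
        if not np.all(np.isfinite(ph)):
            raise ValueError("phases must be finite")


class SpecValidationError(ValueError):
    """Structured validation failure naming the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def ppm_to_offset_hz(ppm: float, carrier_ppm: float, larmor_mhz: float) -> float:
    """Chemical shift (ppm) to rotating-frame offset (Hz).

    ``(ppm - carrier) * larmor``; ppm times MHz is Hz.  Higher ppm maps to a
    higher (positive) offset — one global convention for all nuclei.
    """
    if larmor_mhz <= 0:
        raise SpecValidationError("larmor_mhz", "must be > 0")
    return (ppm - carrier_ppm) * larmor_mhz


def band_grid(band: Band, carrier_ppm: float, larmor_mhz: float) -> np.ndarray:
    """Evenly spaced, endpoint-inclusive offsets (Hz) across a band.

    n_freqs=1 places the single frequency at the band centre, so a user's
    stated band edges are always tested whenever n_freqs >= 2.
    """
    if band.n_freqs < 1:
        raise SpecValidationError("n_freqs", "must be >= 1")
    if band.n_freqs == 1:
        ppms = np.array([(band.lo + band.hi) / 2.0])
    else:
        ppms = np.linspace(band.lo, band.hi, band.n_freqs)
    return (ppms - carrier_ppm) * larmor_mhz


def validate_spec(spec: PulseSpec) -> tuple[PulseSpec, list[str]]:
    """Enforce all invariants; return the spec with a list of warnings.

    Errors (raised): non-positive duration/amplitude/element count, empty or
    inverted bands, ensemble weights not summing to 1.  Warnings (returned):
    element duration below 1 us (hardware-transient guideline), and bands
    with different restraints that overlap in ppm.  Idempotent.
    """
    warnings: list[str] = []
    if spec.larmor_mhz <= 0:
        raise SpecValidationError("larmor_mhz", "must be > 0")
    if spec.n_elements < 1:
        raise SpecValidationError("n_elements", "must be >= 1")
    if spec.duration_us <= 0:
        raise SpecValidationError("duration_us", "must be > 0")
    if spec.peak_amplitude_khz < 0:
        raise SpecValidationError("peak_amplitude_khz", "must be >= 0")
    if len(spec.bands) == 0:
        raise SpecValidationError("bands", "at least one band is required")
    for i, band in enumerate(spec.bands):
        if band.n_freqs < 1:
            raise SpecValidationError(f"bands[{i}].n_freqs", "must be >= 1")
        if band.lo > band.hi:
            raise SpecValidationError(f"bands[{i}]", f"lo {band.lo} > hi {band.hi}")
        if band.lo == band.hi and band.n_freqs != 1:
            raise SpecValidationError(
                f"bands[{i}]", "zero-width band only allowed with n_freqs = 1"
            )
        if not isinstance(band.restraint, Restraint):
            raise SpecValidationError(f"bands[{i}].restraint", "not a Restraint")
        if isinstance(band.restraint, UniversalRotation):
            ax = np.asarray(band.restraint.axis_vector(), dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-8:
                raise SpecValidationError(f"bands[{i}].restraint.axis", "must be unit norm")
        if isinstance(band.restraint, StateToState):
            band.restraint.start_vector()
            band.restraint.finish_vector()

    w = spec.ensemble.weights()
    s = spec.ensemble.scales()
    if np.any(w < 0):
        raise SpecValidationError("ensemble", "weights must be >= 0")
    if np.any(s <= 0):
        raise SpecValidationError("ensemble", "scales must be > 0")
    if abs(w.sum() - 1.0) > 1e-12:
        raise SpecValidationError("ensemble", f"weights sum to {w.sum()!r}, must sum to 1")

    if spec.element_duration_us < 1.0:
        warnings.append(
            f"element duration {spec.element_duration_us:.3g} us is below the 1 us "
            "guideline; spectrometer transients may degrade performance"
        )
    for i in range(len(spec.bands)):
        for j in range(i + 1, len(spec.bands)):
            bi, bj = spec.bands[i], spec.bands[j]
            if bi.restraint != bj.restraint and bi.lo < bj.hi and bj.lo < bi.hi:
                warnings.append(
                    f"bands {i} ({bi.lo}-{bi.hi} ppm) and {j} ({bj.lo}-{bj.hi} ppm) "
                    "overlap with different restraints; the compromise in the overlap "
                    "region is yours"
                )
    return spec, warnings


def with_phases(spec: PulseSpec, phases) -> Pulse:
    """Convenience constructor for a Pulse from a validated spec."""
    return Pulse(spec=spec, phases=np.asarray(phases, dtype=float))
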