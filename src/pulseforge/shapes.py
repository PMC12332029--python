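"""Shaped-pulse file export/import and pulse transforms.

Two common text dialects are supported:

* **Bruker JCAMP-DX shape**: ``##``-prefixed headers, ``##XYPOINTS= (XY..XY)``
  then one ``amplitude, phase`` record per element, amplitude 0-100 (%),
  phase in degrees.
* **Varian/Agilent .RF**: ``#`` comment header then three columns
  ``phase(deg)  amplitude(0-1023)  duration-count``.

Phase-only pulses export at constant maximal amplitude with phases wrapped
to [0, 360); six decimal places, so round-trips recover phases to well
under 1e-4 degrees.

``time_phase_reverse`` reverses the element order and negates every phase.
In the pair representation an element propagator transposes under phase
negation, so the transformed pulse's total propagator is the transpose of
the original's at every (offset, B1) condition — which swaps the roles of
excitation (Z -> -Y) and de-excitation (Y -> Z) at equal infidelity.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .model import Pulse, PulseSpec

__all__ = [
    "ShapeFile",
    "write_shape",
    "read_shape",
    "save_shape",
    "load_shape",
    "pulse_from_shape",
    "time_phase_reverse",
    "ShapeParseError",
]

_DIALECTS = ("bruker", "varian")


class ShapeParseError(ValueError):
    pass


@dataclass
class ShapeFile:
    """Per-element (amplitude, phase) records plus dialect and metadata."""

    dialect: str
    amplitudes: np.ndarray  # fraction of full scale, 0..1
    phases_deg: np.ndarray  # wrapped to [0, 360)
    title: str = "pulseforge shape"
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.phases_deg)

    def text(self) -> str:
        if self.dialect == "bruker":
            return _bruker_text(self)
        if self.dialect == "varian":
            return _varian_text(self)
        raise ValueError(f"unknown dialect {self.dialect!r}")

    def phases_rad(self) -> np.ndarray:
        return np.radians(self.phases_deg)


def write_shape(pulse: Pulse, dialect: str = "bruker", title: str | None = None) -> ShapeFile:
    """Export a phase-only pulse: constant full amplitude, wrapped phases."""
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    deg = np.degrees(np.asarray(pulse.phases, dtype=float)) % 360.0
    spec = pulse.spec
    meta = {
        "nucleus": spec.nucleus,
        "peak_amplitude_khz": spec.peak_amplitude_khz,
        "duration_us": spec.duration_us,
    }
    return ShapeFile(
        dialect=dialect,
        amplitudes=np.ones(len(deg)),
        phases_deg=deg,
        title=title or f"{spec.nucleus} shaped pulse, {spec.duration_us:g} us",
        meta=meta,
    )


def _bruker_text(s: ShapeFile) -> str:
    lines = [
        f"##TITLE= {s.title}",
        "##JCAMP-DX= 5.00 Bruker JCAMP library",
        "##DATA TYPE= Shape Data",
        "##ORIGIN= pulseforge",
        "##OWNER= <nmrsu>",
        f"##DATE= {datetime.date.today().isoformat()}",
        "##MINX= 0.000000e+00",
        "##MAXX= 1.000000e+02",
        "##MINY= 0.000000e+00",
        "##MAXY= 3.600000e+02",
        "##$SHAPE_EXMODE= None",
        "##$SHAPE_TOTROT= 0.000000e+00",
        "##$SHAPE_BWFAC= 0.000000e+00",
        "##$SHAPE_INTEGFAC= 1.000000e+00",
        "##$SHAPE_MODE= 0",
        f"##NPOINTS= {s.n}",
        "##XYPOINTS= (XY..XY)",
    ]
    for amp, ph in zip(s.amplitudes, s.phases_deg):
        lines.append(f"{100.0 * amp:.6f}, {ph:.6f}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def _varian_text(s: ShapeFile) -> str:
    lines = [
        f"# {s.title}",
        "# VERSION       pulseforge",
        "# TYPE          selective",
        f"# STEPS         {s.n}",
        "# phase (deg)  amplitude  duration",
    ]
    for amp, ph in zip(s.amplitudes, s.phases_deg):
        lines.append(f"{ph:12.6f} {1023.0 * amp:10.3f} {1:6d}")
    return "\n".join(lines) + "\n"


def read_shape(text: str, dialect: str | None = None) -> ShapeFile:
    """Parse shape-file text; the dialect is auto-detected if not given."""
    if dialect is None:
        dialect = "bruker" if text.lstrip().startswith("##") else "varian"
    if dialect == "bruker":
        return _parse_bruker(text)
    if dialect == "varian":
        return _parse_varian(text)
    raise ValueError(f"dialect must be one of {_DIALECTS}")


def _parse_bruker(text: str) -> ShapeFile:
    meta: dict = {}
    amps, phases = [], []
    in_points = False
    title = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##END"):
                break
            key, _, val = line[2:].partition("=")
            key, val = key.strip(), val.strip()
            if key == "TITLE":
                title = val
            meta[key] = val
            if key == "XYPOINTS":
                in_points = True
            continue
        if in_points:
            parts = line.split(",")
            if len(parts) != 2:
                raise ShapeParseError(f"line {lineno}: expected 'amplitude, phase'")
            try:
                amps.append(float(parts[0]) / 100.0)
                phases.append(float(parts[1]))
            except ValueError as err:
                raise ShapeParseError(f"line {lineno}: {err}") from err
    if not amps:
        raise ShapeParseError("no XY points found in JCAMP-DX shape")
    npoints = meta.get("NPOINTS")
    if npoints is not None and int(npoints) != len(amps):
        raise ShapeParseError(
            f"NPOINTS={npoints} but {len(amps)} records present"
        )
    return ShapeFile(
        dialect="bruker",
        amplitudes=np.array(amps),
        phases_deg=np.array(phases) % 360.0,
        title=title,
        meta=meta,
    )


def _parse_varian(text: str) -> ShapeFile:
    amps, phases = [], []
    title = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if not title:
                title = line.lstrip("# ").strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ShapeParseError(f"line {lineno}: expected phase/amplitude columns")
        try:
            phases.append(float(parts[0]))
            amps.append(float(parts[1]) / 1023.0)
        except ValueError as err:
            raise ShapeParseError(f"line {lineno}: {err}") from err
    if not amps:
        raise ShapeParseError("no records found in .RF shape")
    return ShapeFile(
        dialect="varian",
        amplitudes=np.array(amps),
        phases_deg=np.array(phases) % 360.0,
        title=title,
        meta={},
    )


def save_shape(pulse: Pulse, path, dialect: str = "bruker", title: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(write_shape(pulse, dialect=dialect, title=title).text())


def load_shape(path, dialect: str | None = None) -> ShapeFile:
    with open(path) as fh:
        return read_shape(fh.read(), dialect=dialect)


def pulse_from_shape(shape: ShapeFile, spec: PulseSpec) -> Pulse:
    """Attach a parsed shape's phases to a spec (element counts must agree)."""
    if shape.n != spec.n_elements:
        raise ValueError(
            f"shape has {shape.n} elements, spec declares {spec.n_elements}"
        )
    return Pulse(spec=spec, phases=shape.phases_rad())


def time_phase_reverse(pulse: Pulse) -> Pulse:
    """Reverse element order and negate every phase (an involution)."""
    return Pulse(spec=pulse.spec, phases=-np.asarray(pulse.phases)[::-1])
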