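"""YAML configuration parsing for batch pulse design.

A config declares one or more pulses, shared optimizer options and output
destinations.  Example::

    optimizer:
      seed: 7
      max_iterations: 2000
    output:
      dialect: bruker
      max_infidelity: 1.0e-2
    pulses:
      - name: n15_u90x
        nucleus: 15N
        larmor_mhz: 60.8
        carrier_ppm: 119.5
        peak_amplitude_khz: 6.85
        duration_us: 250
        n_elements: 250
        bands:
          - {lo: 106, hi: 133, n_freqs: 60, restraint: {type: universal, axis: x, angle: 90}}
        ensemble: default

Restraint types: ``universal`` (axis, angle), ``identity``, ``s2s``
(start, finish cardinal labels), ``xycite``, ``suppression``.  The
ensemble is either ``default`` (0.93/1.00/1.05 weighted 1/4,1/2,1/4) or a
list of ``[scale, weight]`` pairs.  Unknown keys are rejected.  YAML
syntax errors carry line numbers; semantic errors are anchored by pulse
name/index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .model import (
    Band,
    EnsembleDistribution,
    Identity,
    PulseSpec,
    StateToState,
    Suppression,
    UniversalRotation,
    XYcite,
    cardinal_vector,
    default_ensemble,
    validate_spec,
)
from .optimize import HorseraceOptions, OptimizerOptions

__all__ = ["ConfigError", "BatchConfig", "PulseJob", "parse_config", "config_text_for_spec"]


class ConfigError(ValueError):
    pass


@dataclass
class PulseJob:
    name: str
    spec: PulseSpec


@dataclass
class BatchConfig:
    jobs: list[PulseJob]
    optimizer: OptimizerOptions
    output: dict = field(default_factory=dict)


_PULSE_KEYS = {
    "name",
    "nucleus",
    "larmor_mhz",
    "carrier_ppm",
    "peak_amplitude_khz",
    "duration_us",
    "n_elements",
    "bands",
    "ensemble",
}
_BAND_KEYS = {"lo", "hi", "n_freqs", "restraint"}
_OPT_KEYS = {
    "seed",
    "max_iterations",
    "rel_tolerance",
    "rel_window",
    "grad_tolerance",
    "horserace",
}
_TOP_KEYS = {"pulses", "optimizer", "output"}
_OUTPUT_KEYS = {"dir", "dialect", "report", "max_infidelity"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def _parse_restraint(d, where: str):
    if isinstance(d, str):
        d = {"type": d}
    if not isinstance(d, dict) or "type" not in d:
        raise ConfigError(f"{where}: restraint must be a mapping with a 'type'")
    kind = str(d["type"]).lower()
    extra = set(d) - {"type", "axis", "angle", "start", "finish"}
    if extra:
        raise ConfigError(f"{where}: unknown restraint key(s) {sorted(extra)}")
    if kind == "universal":
        axis = d.get("axis", "x")
        if isinstance(axis, str):
            axis = cardinal_vector(axis)
        return UniversalRotation(axis=tuple(axis), angle=float(d.get("angle", 90.0)))
    if kind == "identity":
        return Identity()
    if kind == "s2s":
        return StateToState(start=str(d.get("start", "z")), finish=str(d.get("finish", "-y")))
    if kind == "xycite":
        return XYcite()
    if kind == "suppression":
        return Suppression()
    raise ConfigError(f"{where}: unknown restraint type {kind!r}")


def _parse_ensemble(v, where: str) -> EnsembleDistribution:
    if v is None or v == "default":
        return default_ensemble()
    if not isinstance(v, (list, tuple)) or not v:
        raise ConfigError(f"{where}: ensemble must be 'default' or a list of [scale, weight]")
    pts = []
    for p in v:
        if not isinstance(p, (list, tuple)) or len(p) != 2:
            raise ConfigError(f"{where}: ensemble point {p!r} is not a [scale, weight] pair")
        pts.append((float(p[0]), float(p[1])))
    total = sum(w for _, w in pts)
    if abs(total - 1.0) > 1e-12:
        raise ConfigError(f"{where}: ensemble weights sum to {total!r}, must sum to 1")
    return EnsembleDistribution(points=tuple(pts))


def _parse_pulse(d: dict, index: int) -> PulseJob:
    name = str(d.get("name", f"pulse{index}"))
    where = f"pulses[{index}] ({name})"
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: must be a mapping")
    _check_keys(d, _PULSE_KEYS, where)
    for key in ("nucleus", "larmor_mhz", "carrier_ppm", "peak_amplitude_khz",
                "duration_us", "n_elements", "bands"):
        if key not in d:
            raise ConfigError(f"{where}: missing required key {key!r}")
    bands_raw = d["bands"]
    if not isinstance(bands_raw, list) or not bands_raw:
        raise ConfigError(f"{where}: bands must be a non-empty list")
    bands = []
    for bi, b in enumerate(bands_raw):
        bwhere = f"{where}.bands[{bi}]"
        if not isinstance(b, dict):
            raise ConfigError(f"{bwhere}: must be a mapping")
        _check_keys(b, _BAND_KEYS, bwhere)
        for key in ("lo", "hi", "n_freqs", "restraint"):
            if key not in b:
                raise ConfigError(f"{bwhere}: missing required key {key!r}")
        bands.append(
            Band(
                lo=float(b["lo"]),
                hi=float(b["hi"]),
                n_freqs=int(b["n_freqs"]),
                restraint=_parse_restraint(b["restraint"], bwhere),
            )
        )
    spec = PulseSpec(
        nucleus=str(d["nucleus"]),
        larmor_mhz=float(d["larmor_mhz"]),
        carrier_ppm=float(d["carrier_ppm"]),
        peak_amplitude_khz=float(d["peak_amplitude_khz"]),
        duration_us=float(d["duration_us"]),
        n_elements=int(d["n_elements"]),
        bands=tuple(bands),
        ensemble=_parse_ensemble(d.get("ensemble"), where),
    )
    try:
        validate_spec(spec)
    except ValueError as err:
        raise ConfigError(f"{where}: {err}") from err
    return PulseJob(name=name, spec=spec)


def _parse_optimizer(d: dict | None) -> OptimizerOptions:
    if d is None:
        return OptimizerOptions()
    _check_keys(d, _OPT_KEYS, "optimizer")
    hr = None
    if "horserace" in d and d["horserace"] is not None:
        h = d["horserace"]
        _check_keys(h, {"n_seeds", "checkpoint_iterations"}, "optimizer.horserace")
        hr = HorseraceOptions(
            n_seeds=int(h.get("n_seeds", 50)),
            checkpoint_iterations=int(h.get("checkpoint_iterations", 100)),
        )
    return OptimizerOptions(
        seed=int(d.get("seed", 0)),
        max_iterations=int(d.get("max_iterations", 2000)),
        rel_tolerance=float(d.get("rel_tolerance", 1e-9)),
        rel_window=int(d.get("rel_window", 10)),
        grad_tolerance=float(d.get("grad_tolerance", 1e-10)),
        horserace=hr,
    )


def parse_config(text: str) -> BatchConfig:
    """Parse config text into validated specs + optimizer options + outputs."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"YAML syntax error: {err}") from err
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    pulses = doc.get("pulses")
    if not isinstance(pulses, list) or not pulses:
        raise ConfigError("config: 'pulses' must be a non-empty list")
    jobs = [_parse_pulse(p, i) for i, p in enumerate(pulses)]
    output = doc.get("output") or {}
    _check_keys(output, _OUTPUT_KEYS, "output")
    return BatchConfig(
        jobs=jobs,
        optimizer=_parse_optimizer(doc.get("optimizer")),
        output=output,
    )


def config_text_for_spec(name: str, spec: PulseSpec, opts: OptimizerOptions | None = None) -> str:
    """Serialize a spec back to config text (semantics-preserving round-trip)."""
    def restraint_dict(r):
        if isinstance(r, UniversalRotation):
            return {"type": "universal", "axis": list(r.axis_vector()), "angle": r.angle}
        if isinstance(r, Identity):
            return {"type": "identity"}
        if isinstance(r, StateToState):
            return {"type": "s2s", "start": r.start, "finish": r.finish}
        if isinstance(r, XYcite):
            return {"type": "xycite"}
        if isinstance(r, Suppression):
            return {"type": "suppression"}
        raise TypeError(r)

    doc = {
        "pulses": [
            {
                "name": name,
                "nucleus": spec.nucleus,
                "larmor_mhz": spec.larmor_mhz,
                "carrier_ppm": spec.carrier_ppm,
                "peak_amplitude_khz": spec.peak_amplitude_khz,
                "duration_us": spec.duration_us,
                "n_elements": spec.n_elements,
                "bands": [
                    {
                        "lo": b.lo,
                        "hi": b.hi,
                        "n_freqs": b.n_freqs,
                        "restraint": restraint_dict(b.restraint),
                    }
                    for b in spec.bands
                ],
                "ensemble": [[s, w] for s, w in spec.ensemble.points],
            }
        ]
    }
    if opts is not None:
        doc["optimizer"] = {"seed": opts.seed, "max_iterations": opts.max_iterations}
    return yaml.safe_dump(doc, sort_keys=False)
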