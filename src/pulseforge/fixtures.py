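"""Ready-made design problems from the published pulse catalogue.

These mirror the band definitions used for the 1H/15N/13C/19F pulses of
the adapted HSQC, triple-resonance, water-suppression and broadband-
fluorine experiments: carriers, peak amplitudes, durations and per-band
frequency counts.  Field strengths correspond to a 600 MHz (1H)
spectrometer.  Element counts follow the 1-2 us element-duration
guideline (kept at or under a ~10-degree on-resonance flip per element).

Transform shorthand used in the names: ``u90x``/``u180x`` universal
rotations, ``zz`` the Z->Z hold, ``z-z`` the Z->-Z inversion (both
state-to-state), ``id`` the identity restraint.
"""

from __future__ import annotations

from .model import (
    Band,
    Identity,
    PulseSpec,
    StateToState,
    Suppression,
    UniversalRotation,
    default_ensemble,
    validate_spec,
)

__all__ = ["fixture_specs"]

# Larmor frequencies (MHz) at a 600 MHz (1H) field.
_LARMOR = {"1H": 600.0, "13C": 150.9, "15N": 60.8, "19F": 564.6}

_U90X = UniversalRotation(axis=(1.0, 0.0, 0.0), angle=90.0)
_U180X = UniversalRotation(axis=(1.0, 0.0, 0.0), angle=180.0)
_ZMZ = StateToState(start="z", finish="-z")   # inversion "z-z"
_ZZ = StateToState(start="z", finish="z")     # hold "zz"
_EXCITE = StateToState(start="z", finish="-y")


def fixture_specs() -> dict[str, PulseSpec]:
    """Named catalogue of validated PulseSpecs."""
    co, ca, cb = (158.0, 198.0), (40.0, 78.0), (8.0, 40.0)
    specs = {
        # 15N universal 90x for the HSQC/triple-resonance family.
        "n15_u90x": PulseSpec(
            nucleus="15N",
            larmor_mhz=_LARMOR["15N"],
            carrier_ppm=119.5,
            peak_amplitude_khz=6.85,
            duration_us=250.0,
            n_elements=250,
            bands=(Band(106.0, 133.0, 60, _U90X),),
        ),
        # 1H universal 90x over the full proton window.
        "h1_u90x": PulseSpec(
            nucleus="1H",
            larmor_mhz=_LARMOR["1H"],
            carrier_ppm=4.77,
            peak_amplitude_khz=23.0,
            duration_us=100.0,
            n_elements=100,
            bands=(Band(0.0, 12.0, 96, _U90X),),
        ),
        # Broadband 19F excitation: 300 ppm, 300 frequencies, 2000 us at 20.2 kHz.
        "f19_excite": PulseSpec(
            nucleus="19F",
            larmor_mhz=_LARMOR["19F"],
            carrier_ppm=-100.0,
            peak_amplitude_khz=20.2,
            duration_us=2000.0,
            n_elements=1000,
            bands=(Band(-250.0, 50.0, 300, _EXCITE),),
        ),
        # 13C triple resonance, carrier on Calpha (58 ppm):
        # "CO z-z, Ca u180x, Cb zz", 400 us at 17.6 kHz; 96/96/20 frequencies.
        "c13_co_inv_ca_u180x_cb_hold": PulseSpec(
            nucleus="13C",
            larmor_mhz=_LARMOR["13C"],
            carrier_ppm=58.0,
            peak_amplitude_khz=17.6,
            duration_us=400.0,
            n_elements=400,
            bands=(
                Band(*co, 96, _ZMZ),
                Band(*ca, 96, _U180X),
                Band(*cb, 20, _ZZ),
            ),
        ),
        # Detect Ca, decouple CO/Cb: CO/Cb inverted, Ca identity (carrier 58).
        "c13_ca_id_cocb_inv": PulseSpec(
            nucleus="13C",
            larmor_mhz=_LARMOR["13C"],
            carrier_ppm=58.0,
            peak_amplitude_khz=17.6,
            duration_us=400.0,
            n_elements=400,
            bands=(
                Band(*co, 96, _ZMZ),
                Band(*ca, 96, Identity()),
                Band(*cb, 20, _ZMZ),
            ),
        ),
        # Detect CO, decouple Ca/Cb: CO identity, Ca/Cb inverted (carrier 176).
        "c13_co_id_cacb_inv": PulseSpec(
            nucleus="13C",
            larmor_mhz=_LARMOR["13C"],
            carrier_ppm=176.0,
            peak_amplitude_khz=17.6,
            duration_us=200.0,
            n_elements=200,
            bands=(
                Band(*co, 96, Identity()),
                Band(*ca, 96, _ZMZ),
                Band(*cb, 20, _ZMZ),
            ),
        ),
        # INEPT CO transfer: CO u180x, Ca/Cb inverted (carrier 176).
        "c13_co_u180x_cacb_inv": PulseSpec(
            nucleus="13C",
            larmor_mhz=_LARMOR["13C"],
            carrier_ppm=176.0,
            peak_amplitude_khz=17.6,
            duration_us=200.0,
            n_elements=200,
            bands=(
                Band(*co, 96, _U180X),
                Band(*ca, 96, _ZMZ),
                Band(*cb, 20, _ZMZ),
            ),
        ),
        # 1H water suppression: universal rotations on CH/NH, prefix-hold on water.
        "h1_watersup_u90x": PulseSpec(
            nucleus="1H",
            larmor_mhz=_LARMOR["1H"],
            carrier_ppm=4.77,
            peak_amplitude_khz=9.76,
            duration_us=2000.0,
            n_elements=1000,
            bands=(
                Band(-1.0, 3.5, 15, _U90X),
                Band(4.65, 4.85, 10, Suppression()),
                Band(6.5, 10.0, 20, _U90X),
            ),
        ),
    }
    for name, spec in specs.items():
        validate_spec(spec)
        assert spec.ensemble == default_ensemble()
    return specs
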