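"""Synthetic inputs for every stage of the pipeline.

The real validation experiment recorded drop fluorescence through a
fibre-coupled spectrometer; its raw spectra are not published. The
generator emulates the measurement: four spectral components (residual
455 nm diode scatter; Fluo-5N emission peaking at 515 nm; Ca-bound Fura
Red at 640 nm; Ca-free Fura Red at 670 nm) as max-normalised Gaussian
surrogates, calcium-dependent amplitudes rising as a*(1-exp(-t/tau)) with
the interaction time set by tape speed, intensity scaling with the
1/speed residence time, and additive Gaussian noise. Ground truth is
returned next to every dataset so fits can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .mixing_pipeline import MixingConfig
from .spectral_fit import (DEFAULT_REFERENCE_SPEED, ComponentSet, Spectrum)

#: (name, lambda_max nm, FWHM nm) of the surrogate components
DEFAULT_PEAKS = (
    # the diode profile is wider than the LED line so its scatter tail
    # genuinely reaches into the 510-750 nm fit window
    ("diode", 455.0, 40.0),
    ("fluo", 515.0, 60.0),
    ("fura_plus", 640.0, 60.0),
    ("fura_minus", 670.0, 60.0),
)


def make_component_spectra(grid_nm=None, peaks=DEFAULT_PEAKS) -> ComponentSet:
    """Max-normalised Gaussian surrogate components on a wavelength grid."""
    if grid_nm is None:
        grid_nm = np.arange(450.0, 801.0, 1.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    components, centres = {}, {}
    for name, lmax, fwhm in peaks:
        if not fwhm > 0:
            raise ValidationError(f"FWHM of {name!r} must be > 0, got {fwhm}")
        if not (grid_nm[0] <= lmax <= grid_nm[-1]):
            raise ValidationError(
                f"peak {name!r} at {lmax} nm lies outside the grid "
                f"[{grid_nm[0]}, {grid_nm[-1]}] nm")
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = np.exp(-0.5 * ((grid_nm - lmax) / sigma) ** 2)
        components[name] = y / y.max()
        centres[name] = lmax
    return ComponentSet(grid_nm, components, centres)


def synthesize_measurement_series(comps: ComponentSet, tau_map: dict,
                                  amplitude_map: dict, tape_speeds_mm_s,
                                  path_length_mm: float = 60.0,
                                  noise_sd: float = 0.02, seed: int = 0,
                                  reference_speed: float = DEFAULT_REFERENCE_SPEED,
                                  diode_level: float = 1.0):
    """Forward-model a tape-speed series of noisy spectra.

    For each speed v the interaction time is t = path_length / v; the
    calcium-dependent coefficients follow a*(1-exp(-t/tau)); the Ca-free
    Fura Red coefficient decays complementarily from its amplitude; the
    clean linear combination is scaled by the residence-time factor
    reference_speed / v and Gaussian noise of sd ``noise_sd`` x (peak
    intensity in the fit window) is added. Returns (spectra, ground_truth).
    """
    for name in ("fluo", "fura_plus"):
        if name not in tau_map or not tau_map[name] > 0:
            raise ValidationError(f"tau_map[{name!r}] must be present and > 0")
        if name not in amplitude_map or not amplitude_map[name] > 0:
            raise ValidationError(f"amplitude_map[{name!r}] must be present and > 0")
    tape_speeds = np.asarray(tape_speeds_mm_s, dtype=float)
    if np.any(tape_speeds <= 0):
        raise ValidationError("tape speeds must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wl = comps.wavelengths_nm
    spectra: list[Spectrum] = []
    truth = {"tau_s": dict(tau_map), "amplitude": dict(amplitude_map),
             "path_length_mm": path_length_mm, "reference_speed": reference_speed,
             "seed": seed, "points": []}
    a_minus = amplitude_map.get("fura_minus", amplitude_map["fura_plus"])
    for v in tape_speeds:
        t = path_length_mm / v
        coeffs = {
            "diode": diode_level,
            "fluo": amplitude_map["fluo"] * (1.0 - np.exp(-t / tau_map["fluo"])),
            "fura_plus": amplitude_map["fura_plus"]
            * (1.0 - np.exp(-t / tau_map["fura_plus"])),
            "fura_minus": a_minus * np.exp(-t / tau_map["fura_plus"]),
        }
        clean = sum(coeffs[n] * comps.components[n] for n in coeffs)
        residence = reference_speed / v
        y = clean * residence
        if noise_sd > 0:
            window = (wl >= 510.0) & (wl <= 750.0)
            sd = noise_sd * np.abs(y[window]).max()
            y = y + rng.normal(0.0, sd, size=y.shape)
        spectra.append(Spectrum(wl.copy(), y, tape_speed_mm_s=float(v),
                                meta={"interaction_time_s": t}))
        truth["points"].append({"tape_speed_mm_s": float(v),
                                "t_s": float(t), "coefficients": coeffs})
    return spectra, truth


@dataclass
class ScenarioFixture:
    """A named, fully specified runnable configuration with ground truth."""

    name: str
    mixing: MixingConfig | None
    components: ComponentSet
    ground_truth: dict
    seed: int
    provenance: dict = field(default_factory=dict)


def _ca_dye_mixing(regime: str, seed: int) -> MixingConfig:
    # the dye-validation drop recipe: 4 nL main drop with 1 mM of each
    # indicator, three 60 pL injector drops of 100 mM CaCl2
    return MixingConfig(regime=regime, ade_volume_nL=4.0, pei_volume_pL=60.0,
                        n_pei_drops=3, ca_concentration_M=0.1,
                        dye_concentration_M=1e-3, seed=seed)


def make_scenario(name: str, seed: int = 0) -> ScenarioFixture:
    """Canned, fully-parameterised scenarios for the in-study experiments."""
    comps = make_component_spectra()
    prov_dyes = {
        "ade_volume_nL": "acoustic-ejection crystal/dye drop volume (4 nL)",
        "pei_volume_pL": "injector drop volume with the 100 µm orifice (60 pL)",
        "n_pei_drops": "one to five CaCl2 drops dispensed; three simulated",
        "ca_concentration_M": "CaCl2 stock concentration (100 mM)",
        "dye_concentration_M": "1 mM each of Fura Red and Fluo-5N",
    }
    if name == "ca_dye_fluorescence":
        return ScenarioFixture(name, _ca_dye_mixing("diffusion_only", seed), comps,
                               {"tau_map": {"fluo": 0.15, "fura_plus": 0.10},
                                "amplitude_map": {"fluo": 1.0, "fura_plus": 0.5,
                                                  "fura_minus": 0.5}},
                               seed, prov_dyes)
    if name == "fig1b_diffusion":
        return ScenarioFixture(name, _ca_dye_mixing("diffusion_only", seed), comps,
                               {}, seed, prov_dyes)
    if name == "fig1b_massflow":
        cfg = _ca_dye_mixing("mass_flow", seed)
        prov = dict(prov_dyes,
                    v_rel_m_s="relative drop impact velocity, 1-2 m/s range")
        return ScenarioFixture(name, cfg, comps, {}, seed, prov)
    if name == "hewl_glcnac":
        cfg = MixingConfig(regime="mass_flow", ade_volume_nL=3.0, pei_volume_pL=120.0,
                           n_pei_drops=2, ca_concentration_M=0.226,
                           dye_concentration_M=0.0, seed=seed)
        return ScenarioFixture(
            name, cfg, comps,
            {"substrate": "GlcNAc", "stock_M": 0.226, "drops": (2, 6),
             "final_mM": (16.7, 43.7)},
            seed,
            {"ade_volume_nL": "crystal slurry drop volume (~3 nL)",
             "pei_volume_pL": "substrate drop volume (~120 pL, 100 µm orifice)",
             "ca_concentration_M": "GlcNAc stock 50 mg/mL = 226 mM"})
    if name == "ctxm_ertapenem":
        cfg = MixingConfig(regime="mass_flow", ade_volume_nL=3.0, pei_volume_pL=120.0,
                           n_pei_drops=4, ca_concentration_M=0.8,
                           dye_concentration_M=0.0, seed=seed)
        return ScenarioFixture(
            name, cfg, comps,
            {"substrate": "ertapenem", "stock_M": 0.8, "drops": 4,
             "final_mM": 110.3},
            seed,
            {"ade_volume_nL": "crystal slurry drop volume (~3 nL)",
             "pei_volume_pL": "substrate drop volume (~120 pL)",
             "ca_concentration_M": "ertapenem stock 398 mg/mL = 0.8 M"})
    raise ValidationError(
        f"unknown scenario {name!r}; known: ca_dye_fluorescence, fig1b_diffusion, "
        "fig1b_massflow, hewl_glcnac, ctxm_ertapenem")
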