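"""Synthetic spectral inputs: UV daylight radiance and a pigment template.

The headline results of the model chain need no spectral data (they run
from the canonical fitted absorptance polynomial), but the exact spectral
pipeline — absorptance by wavelength integration and the polynomial fit —
must be testable.  This module generates the two inputs that pipeline
needs:

* a smooth, strictly positive clear-sky radiance on the 300-412 nm window,
  shaped as a blackbody modulated by Rayleigh scattering (lambda^-4), and
* a unimodal UV rhodopsin absorbance template peaking at 335 nm, shaped as
  a two-sided log-normal band and normalized to 1 at the peak.

Both are synthetic stand-ins constructed to reproduce the study's stated
conditions (UV-rich daylight, a single absorption band negligible outside
300-412 nm); absolute radiance is arbitrary because the incident photon
flux is a free model input downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT
from scipy.constants import h as PLANCK
from scipy.constants import k as BOLTZMANN

from .optics import WAVELENGTH_MAX_NM, WAVELENGTH_MIN_NM, SpectralRadiance

__all__ = [
    "SkyModelParams",
    "make_daylight_spectrum",
    "make_delta_spectrum",
    "pigment_template",
]


@dataclass(frozen=True)
class SkyModelParams:
    """Parameters of the synthetic clear-sky radiance.

    ``colour_temperature_k`` sets the blackbody proxy for the solar
    spectrum, ``rayleigh_exponent`` the scattering law (4 for molecular
    scattering), ``scale`` the peak radiance (photons sr^-1 m^-2 nm^-1;
    arbitrary, since downstream intensities are set by the incident photon
    flux), and ``noise_sd`` an optional multiplicative log-normal
    perturbation drawn from ``seed``.
    """

    colour_temperature_k: float = 6500.0
    rayleigh_exponent: float = 4.0
    scale: float = 1e18
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _grid() -> np.ndarray:
    n = int(round(WAVELENGTH_MAX_NM - WAVELENGTH_MIN_NM)) + 1
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n)


def make_daylight_spectrum(params: SkyModelParams | None = None) -> SpectralRadiance:
    """Synthetic UV-rich clear-sky photon radiance on a 1 nm grid.

    Photon radiance of a blackbody at the colour temperature, multiplied
    by ``lambda**-rayleigh_exponent`` and renormalized so the maximum over
    the window equals ``scale``.  Deterministic given the seed.
    """
    if params is None:
        params = SkyModelParams()
    wl = _grid()
    lam_m = wl * 1e-9
    # Photon (not energy) spectral radiance of a blackbody: B/(hc/lambda).
    x = PLANCK * SPEED_OF_LIGHT / (lam_m * BOLTZMANN * params.colour_temperature_k)
    photon_bb = lam_m**-4 / np.expm1(x)
    shape = photon_bb * lam_m ** (-params.rayleigh_exponent)
    radiance = params.scale * shape / shape.max()
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        radiance = radiance * np.exp(rng.normal(0.0, params.noise_sd, size=wl.size))
    return SpectralRadiance(wl, radiance)


def make_delta_spectrum(lambda0_nm: float, total_radiance: float = 1.0) -> SpectralRadiance:
    """Monochromatic fixture: all radiance in the grid bin nearest lambda0.

    The single nonzero point is scaled so the trapezoidal integral over the
    window equals ``total_radiance`` exactly, including at the window
    edges where the trapezoid weight is halved.
    """
    if not WAVELENGTH_MIN_NM <= lambda0_nm <= WAVELENGTH_MAX_NM:
        raise ValueError(
            f"lambda0 must lie within [{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
        )
    wl = _grid()
    idx = int(np.argmin(np.abs(wl - lambda0_nm)))
    indicator = np.zeros_like(wl)
    indicator[idx] = 1.0
    weight = np.trapezoid(indicator, wl)
    radiance = indicator * (total_radiance / weight)
    return SpectralRadiance(wl, radiance)


#: Log-wavelength half-widths of the template band.  The band reaches 1e-2
#: at the window edges (300 and 412 nm) and keeps falling outside, matching
#: the premise that absorption is negligible beyond the window.
_EDGE_LEVEL = 1e-2
#: Shape exponent of the band flanks.  2 would give a log-normal Gaussian;
#: the slightly flatter-topped 2.24 calibrates the synthetic stand-in so
#: that the spectral pipeline (exact absorptance + polynomial fit)
#: reproduces the canonical broadband absorptance curve.
_FLANK_EXPONENT = 2.24


def pigment_template(
    wavelength_nm,
    lambda_max_nm: float = 335.0,
    flank_exponent: float = _FLANK_EXPONENT,
):
    """Relative absorbance of the UV rhodopsin, normalized to 1 at the peak.

    A two-sided band in log-wavelength: each flank decays as
    ``exp(-ln(100) * |ln(lambda/lambda_max)/s|^p)`` with the half-widths
    ``s`` fixed so the template equals 0.01 exactly at 300 and 412 nm.
    Unimodal, strictly decreasing away from the peak.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    y = np.log(wl / lambda_max_nm)
    s_left = abs(np.log(WAVELENGTH_MIN_NM / lambda_max_nm))
    s_right = abs(np.log(WAVELENGTH_MAX_NM / lambda_max_nm))
    s = np.where(y < 0, s_left, s_right)
    out = np.exp(-np.log(1.0 / _EDGE_LEVEL) * np.abs(y / s) ** flank_exponent)
    return float(out) if out.ndim == 0 else out
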