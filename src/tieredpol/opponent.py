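"""Opponent coding of polarization angle by R7 and R8.

The opponent unit subtracts R8's contrast signal from R7's and adds
intrinsic (neural) noise.  Contrast ``q = M / M_bg`` normalizes each
receptor's transduction to its response to unpolarized background light of
the same intensity, making the opponent output intensity-invariant in the
unsaturated regime.  Two coding metrics are derived from the noisy output
``Q(theta)``:

* the number of discriminable polarization angles, a Riemannian sum of
  just-noticeable differences (one noise standard deviation each) along
  the 0-90 degree stimulus path; and
* the mutual information between angle and output, for a uniform prior
  over angle and Gaussian channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Callable

import numpy as np

from .optics import (
    CANONICAL_ABSORPTANCE,
    DichroicAbsorption,
    PolarizedLight,
    TieredPairGeometry,
    broadband_absorption_rates,
    polarization_sensitivity,
)
from .transduction import (
    MicrovillarArray,
    binomial_transduction_moments,
    segment_absorption_profile,
)

__all__ = [
    "OpponentConfig",
    "OpponentModel",
    "contrast_signal",
    "signal_range",
    "snr",
    "opponent_response",
]


@dataclass(frozen=True)
class OpponentConfig:
    """Stimulus and noise settings for the opponent unit.

    ``sigma_in_sq`` is the variance of the contrast-referred intrinsic
    noise for a 1 s integration; for a window ``tau`` it scales as
    ``sigma_in_sq / tau`` and enters twice, once per photoreceptor.
    """

    total_flux: float
    degree: float = 0.1
    sigma_in_sq: float = 5e-5
    tau_ms: float = 90.0
    saturation: bool = False

    def __post_init__(self) -> None:
        if self.total_flux < 0:
            raise ValueError("total_flux must be non-negative")
        if not 0.0 <= self.degree <= 1.0:
            raise ValueError("degree of polarization must lie in [0, 1]")
        if self.sigma_in_sq < 0:
            raise ValueError("sigma_in_sq must be non-negative")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be positive")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def contrast_signal(mean_count: float, bg_mean_count: float) -> float:
    """Contrast ``q = M / M_bg`` of a transduced count against background."""
    if bg_mean_count <= 0:
        raise ZeroDivisionError(
            "background transduction is zero: degenerate geometry (no "
            "absorbing length) cannot define a contrast signal"
        )
    return mean_count / bg_mean_count


def signal_range(ps: float, degree: float) -> float:
    """Contrast signal range ``2 d (PS - 1) / (PS + 1)`` of one receptor."""
    if ps < 1:
        raise ValueError("polarization sensitivity must be >= 1")
    if not 0.0 <= degree <= 1.0:
        raise ValueError("degree of polarization must lie in [0, 1]")
    return 2.0 * degree * (ps - 1.0) / (ps + 1.0)


def snr(delta_q: float, m_bg: float, tau_ms: float) -> float:
    """Photon-noise-limited SNR, ``delta_q * sqrt(tau * M_bg)``.

    Identical whether computed on contrasts or raw counts, because both
    the signal range and the noise standard deviation are divided by the
    same background count.
    """
    if m_bg <= 0:
        raise ValueError("background transduction rate must be positive")
    return delta_q * np.sqrt(tau_ms * 1e-3 * m_bg)


def opponent_response(q7, q8):
    """Opponent output ``Q = q7 - q8`` on a shared angle grid."""
    return np.asarray(q7, dtype=float) - np.asarray(q8, dtype=float)


# ---------------------------------------------------------------------------
# The opponent unit
# ---------------------------------------------------------------------------


class OpponentModel:
    """Opponent unit for a fixed CRP geometry, illumination and noise budget.

    Computes contrast signals, opponent output and total noise on arbitrary
    angle grids, plus the two coding metrics.  In the unsaturated regime the
    closed forms in PS are used; with saturation every quantity is built
    from per-segment binomial transduction moments.
    """

    def __init__(
        self,
        pair: TieredPairGeometry,
        dichroic: DichroicAbsorption,
        config: OpponentConfig,
        fa: Callable[[float], float] = CANONICAL_ABSORPTANCE,
        array: MicrovillarArray | None = None,
    ) -> None:
        self.pair = pair
        self.dichroic = dichroic
        self.config = config
        self.fa = fa
        self.array = array if array is not None else MicrovillarArray()
        self.tau_s = config.tau_ms * 1e-3

        bg = PolarizedLight(config.total_flux, 0.0, 0.0)
        bg_rates = broadband_absorption_rates(pair, dichroic, bg, fa)
        #: Background absorption rates (photons/s); transduction equals
        #: absorption when saturation is off.
        self.bg_rate7 = bg_rates.a7
        self.bg_rate8 = bg_rates.a8
        if self.bg_rate7 <= 0 or self.bg_rate8 <= 0:
            raise ZeroDivisionError(
                "a receptor with zero background absorption cannot form a "
                "contrast signal; geometry is degenerate"
            )

        self.ps7 = polarization_sensitivity(7, pair, dichroic, "broadband", fa)
        self.ps8 = polarization_sensitivity(8, pair, dichroic, "broadband", fa)

        if config.saturation:
            self._profile = segment_absorption_profile(pair, dichroic, self.array, fa)
            self._bg_moments = self._saturated_moments(np.array([45.0]), degree=0.0)

    # -- transduction ------------------------------------------------------

    def _polarized_fluxes(self, theta_deg: np.ndarray, degree: float):
        cos2t = np.cos(2.0 * np.radians(theta_deg))
        n_par = self.config.total_flux * (1.0 + degree * cos2t) / 2.0
        return n_par, self.config.total_flux - n_par

    def _saturated_moments(self, theta_deg: np.ndarray, degree: float | None = None):
        """Summed binomial moments for R7 and R8 at each angle."""
        if degree is None:
            degree = self.config.degree
        n_par, n_perp = self._polarized_fluxes(theta_deg, degree)
        prof = self._profile
        out = []
        for coef_par, coef_perp, n_m in (
            (prof.coef_par_7, prof.coef_perp_7, prof.n_m_7),
            (prof.coef_par_8, prof.coef_perp_8, prof.n_m_8),
        ):
            if coef_par.size == 0:
                zeros = np.zeros_like(np.atleast_1d(theta_deg), dtype=float)
                out.extend([zeros, zeros])
                continue
            rates = np.outer(coef_par, n_par) + np.outer(coef_perp, n_perp)
            mean, var = binomial_transduction_moments(
                rates,
                np.asarray(n_m)[:, None],
                self.array.dead_time_ms,
                self.config.tau_ms,
            )
            out.extend([mean.sum(axis=0), var.sum(axis=0)])
        return tuple(out)  # mean7, var7, mean8, var8 (counts per tau)

    # -- signals and noise -------------------------------------------------

    def contrasts(self, theta_deg) -> tuple[np.ndarray, np.ndarray]:
        """Contrast signals ``(q7, q8)`` at the given angles (degrees)."""
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        d = self.config.degree
        if not self.config.saturation:
            cos2t = np.cos(2.0 * np.radians(theta))
            q7 = 1.0 + d * (self.ps7 - 1.0) / (self.ps7 + 1.0) * cos2t
            q8 = 1.0 - d * (self.ps8 - 1.0) / (self.ps8 + 1.0) * cos2t
            return q7, q8
        mean7, _, mean8, _ = self._saturated_moments(theta)
        bg7, _, bg8, _ = self._bg_moments
        return mean7 / bg7[0], mean8 / bg8[0]

    def contrast_noise_variances(self, theta_deg) -> tuple[np.ndarray, np.ndarray]:
        """Photon-noise variances of ``q7`` and ``q8`` per integration time."""
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        if not self.config.saturation:
            q7, q8 = self.contrasts(theta)
            # Var(q) = Var(M^tau)/(M_bg^tau)^2 = M(theta) / (M_bg^2 tau)
            v7 = q7 / (self.bg_rate7 * self.tau_s)
            v8 = q8 / (self.bg_rate8 * self.tau_s)
            return v7, v8
        _, var7, _, var8 = self._saturated_moments(theta)
        bg7, _, bg8, _ = self._bg_moments
        return var7 / bg7[0] ** 2, var8 / bg8[0] ** 2

    def opponent(self, theta_deg) -> np.ndarray:
        """Mean opponent output ``Q(theta) = q7 - q8``."""
        q7, q8 = self.contrasts(theta_deg)
        return opponent_response(q7, q8)

    def noise_variance(self, theta_deg) -> np.ndarray:
        """Total opponent noise variance: photon terms plus ``2 sigma_in^2 / tau``."""
        v7, v8 = self.contrast_noise_variances(theta_deg)
        return v7 + v8 + 2.0 * self.config.sigma_in_sq / self.tau_s

    @cached_property
    def _theta_fine(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, 901)

    def signal_range_q(self) -> float:
        """Opponent signal range ``dQ = max Q - min Q`` over all angles.

        Equals ``dq7 + dq8`` exactly in the unsaturated regime.
        """
        if not self.config.saturation:
            return signal_range(self.ps7, self.config.degree) + signal_range(
                self.ps8, self.config.degree
            )
        q = self.opponent(self._theta_fine)
        return float(q.max() - q.min())

    def receptor_snr(self) -> tuple[float, float]:
        """Photon-noise-limited SNR of R7 and R8 contrast signals.

        Signal range over noise standard deviation at the background-
        equivalent angle (45 deg).  Without saturation this equals the
        closed form ``2 d (PS-1)/(PS+1) sqrt(tau M_bg)``.
        """
        theta = self._theta_fine
        q7, q8 = self.contrasts(theta)
        v7, v8 = self.contrast_noise_variances(np.array([45.0]))
        snr7 = float((q7.max() - q7.min()) / np.sqrt(v7[0]))
        snr8 = float((q8.max() - q8.min()) / np.sqrt(v8[0]))
        return snr7, snr8

    def effective_ps(self) -> tuple[float, float]:
        """PS of R7 and R8 from transduced means under fully polarized light.

        Equals the optical PS when saturation is off; saturation compresses
        the max/min ratio because the preferred angle saturates first.
        """
        if not self.config.saturation:
            return self.ps7, self.ps8
        m7, _, m8, _ = self._saturated_moments(np.array([0.0, 90.0]), degree=1.0)
        return float(m7[0] / m7[1]), float(m8[1] / m8[0])

    # -- coding metrics ----------------------------------------------------

    def discriminability(self, theta_deg) -> np.ndarray:
        """Inverse just-noticeable angle difference, 1/deg, at each angle.

        The jnd is the angle step whose opponent-signal change equals one
        noise standard deviation (local linearization).  At 0 and 90
        degrees the gradient vanishes and discriminability is 0.
        """
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        sigma = np.sqrt(self.noise_variance(theta))
        if not self.config.saturation:
            amp = self.config.degree * (
                (self.ps7 - 1.0) / (self.ps7 + 1.0)
                + (self.ps8 - 1.0) / (self.ps8 + 1.0)
            )
            grad = np.abs(
                -2.0 * amp * np.sin(2.0 * np.radians(theta)) * np.pi / 180.0
            )
        else:
            h = 0.01
            grad = np.abs(
                self.opponent(np.clip(theta + h, 0, 90))
                - self.opponent(np.clip(theta - h, 0, 90))
            ) / (np.clip(theta + h, 0, 90) - np.clip(theta - h, 0, 90))
        return grad / sigma

    def discriminable_angles(self, n: int = 900) -> float:
        """Number of discriminable polarization angles across 0-90 degrees.

        Riemannian sum of opponent-signal steps, each divided by the local
        noise standard deviation (jnd threshold of one SD).
        """
        theta = np.linspace(0.0, 90.0, n + 1)
        q = self.opponent(theta)
        sigma = np.sqrt(self.noise_variance(theta[:-1]))
        return float(np.sum(np.abs(np.diff(q)) / sigma))

    def mutual_information(self, theta_n: int = 512, q_n: int = 2001) -> float:
        """Mutual information I(Q; theta) in bits per integration time.

        The angle prior is uniform on [0, 90) degrees and the channel is
        Gaussian with angle-dependent variance, so
        ``I = h(Q) - h(Q | theta)`` with ``f(Q)`` the angle-marginalized
        Gaussian mixture, evaluated by trapezoidal quadrature.
        """
        theta = np.linspace(0.0, 90.0, theta_n + 1)
        q_mean = self.opponent(theta)
        var = self.noise_variance(theta)
        if np.any(var <= 0):
            raise ValueError(
                "opponent noise variance must be positive everywhere; supply "
                "intrinsic noise or nonzero photon flux"
            )
        sigma = np.sqrt(var)
        lo = float(np.min(q_mean - 8.0 * sigma))
        hi = float(np.max(q_mean + 8.0 * sigma))
        q_grid = np.linspace(lo, hi, q_n)
        # f(Q) = average over theta of the conditional Gaussians (the angle
        # grid closes the interval, so trapezoid weights apply in theta too).
        z = (q_grid[None, :] - q_mean[:, None]) / sigma[:, None]
        cond = np.exp(-0.5 * z**2) / (sigma[:, None] * np.sqrt(2.0 * np.pi))
        f_q = np.trapezoid(cond, theta, axis=0) / 90.0
        f_q = np.maximum(f_q, 1e-300)
        h_q = -np.trapezoid(f_q * np.log2(f_q), q_grid)
        h_cond = np.trapezoid(0.5 * np.log2(2.0 * np.pi * np.e * var), theta) / 90.0
        return float(h_q - h_cond)
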