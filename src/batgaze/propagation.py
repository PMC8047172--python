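"""Acoustic propagation: spreading loss and atmospheric absorption.

Absorption follows the ISO 9613-1 analytic model (classical plus molecular
relaxation of O2 and N2), evaluated by default at 20 degrees C, 50 %
relative humidity and standard pressure — roughly 0.3 dB/m at 25 kHz and
1.3 dB/m at 40 kHz, which is why high-frequency level-based beam
estimation must correct for range-dependent absorption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Environment", "atmospheric_absorption_db_per_m", "spreading_loss_db"]

#: Reference distance for source levels (metres): levels are quoted "at 10 cm".
REF_DISTANCE_M = 0.10


def atmospheric_absorption_db_per_m(freq_hz, temperature_c: float = 20.0,
                                    relative_humidity: float = 50.0,
                                    pressure_kpa: float = 101.325) -> np.ndarray:
    """Pure-tone atmospheric absorption coefficient alpha(f), dB per metre.

    ISO 9613-1 formulation; vectorised over frequency.
    """
    f = np.asarray(freq_hz, float)
    T = temperature_c + 273.15
    T0 = 293.15
    T01 = 273.16
    p = pressure_kpa
    pr = 101.325
    # molar concentration of water vapour (%)
    C = -6.8346 * (T01 / T) ** 1.261 + 4.6151
    psat_over_pr = 10.0 ** C
    h = relative_humidity * psat_over_pr * (pr / p)
    # relaxation frequencies of O2 and N2 (Hz)
    frO = (p / pr) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    frN = (p / pr) * (T / T0) ** -0.5 * (9.0 + 280.0 * h * np.exp(-4.170 * ((T / T0) ** (-1.0 / 3.0) - 1.0)))
    f2 = f ** 2
    alpha = 8.686 * f2 * (
        1.84e-11 * (pr / p) * (T / T0) ** 0.5
        + (T / T0) ** -2.5 * (
            0.01275 * np.exp(-2239.1 / T) / (frO + f2 / frO)
            + 0.1068 * np.exp(-3352.0 / T) / (frN + f2 / frN)
        )
    )
    return alpha


def spreading_loss_db(distance_m, ref_distance_m: float = REF_DISTANCE_M) -> np.ndarray:
    """Spherical-spreading loss 20 log10(r / r_ref) in dB (positive = loss)."""
    r = np.asarray(distance_m, float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return 20.0 * np.log10(r / ref_distance_m)


@dataclass(frozen=True)
class Environment:
    """Propagation environment for rendering and for level correction."""

    c_mps: float = 344.0                 # speed of sound (about 20 C)
    temperature_c: float = 20.0
    relative_humidity: float = 50.0
    noise_db: float = -65.0              # per-channel white-noise RMS, dB re full
                                         # scale; with the default chirp source
                                         # level this puts the median per-call
                                         # detection SNR near 20 dB
    ref_distance_m: float = REF_DISTANCE_M
    absorption_scale: float = 1.0        # 0 disables absorption (idealised medium)

    def absorption_db_per_m(self, freq_hz) -> np.ndarray:
        return self.absorption_scale * atmospheric_absorption_db_per_m(
            freq_hz, self.temperature_c, self.relative_humidity)

    def path_loss_db(self, distance_m, freq_hz) -> np.ndarray:
        """Total one-way loss: spherical spreading plus absorption (dB)."""
        return spreading_loss_db(distance_m, self.ref_distance_m) + \
            np.asarray(distance_m, float) * self.absorption_db_per_m(freq_hz)
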