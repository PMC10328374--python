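"""Synthetic Raman spectra of cortical bone.

Spectra are a sum of Gaussian/Lorentzian band profiles, a polynomial
baseline, and i.i.d. Gaussian noise on a uniform axis.  The attached truth
metrics are evaluated analytically on a fine grid of the noiseless,
baseline-free band sum, independently of the measurement pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..raman import BANDS, RamanSpectrum

__all__ = ["Band", "SpectrumTruth", "gen_raman_spectrum", "default_bands"]


@dataclass(frozen=True)
class Band:
    center: float   # cm^-1
    height: float   # counts
    width: float    # Gaussian sigma or Lorentzian HWHM, cm^-1
    shape: str = "gaussian"  # gaussian | lorentzian

    def profile(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.height * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)
        if self.shape == "lorentzian":
            return self.height / (1.0 + ((x - self.center) / self.width) ** 2)
        raise ValueError(f"unknown band shape {self.shape!r}")


def default_bands(
    nu1_sigma: float = 6.0,
    mineral_scale: float = 1.0,
) -> list[Band]:
    """Characteristic mineral and matrix bands of bone tissue."""
    return [
        Band(430.0, 180.0 * mineral_scale, 9.0),     # nu2 PO4
        Band(960.0, 1000.0 * mineral_scale, nu1_sigma),  # nu1 PO4
        Band(1070.0, 150.0 * mineral_scale, 8.0),    # nu1 CO3
        Band(1245.0, 220.0, 18.0),                   # amide III
        Band(1450.0, 260.0, 12.0),                   # CH2 wag
        Band(1495.0, 40.0, 8.0),                     # PEN (small)
        Band(1660.0, 320.0, 11.0),                   # amide I (mature)
        Band(1690.0, 200.0, 11.0),                   # amide I shoulder
    ]


@dataclass
class SpectrumTruth:
    bands: Sequence[Band] = field(default_factory=default_bands)
    baseline_coeffs: Sequence[float] = ()   # polynomial, highest power first
    noise_sd: float = 0.0                   # counts
    true_metrics: dict = field(init=False)

    def __post_init__(self) -> None:
        for b in self.bands:
            if not 280.0 <= b.center <= 2000.0:
                raise ValueError("band centers must lie within 280-2000 cm^-1")
            if b.width <= 0:
                raise ValueError("band widths must be > 0")
        self.true_metrics = _analytic_metrics(self.bands)

    def band_sum(self, x: np.ndarray) -> np.ndarray:
        total = np.zeros_like(x, dtype=float)
        for b in self.bands:
            total += b.profile(x)
        return total


def _analytic_metrics(bands: Sequence[Band], step: float = 0.01) -> dict:
    """Metric ground truth from fine-grid integration of the pure band sum."""

    def sum_profile(x):
        total = np.zeros_like(x)
        for b in bands:
            total += b.profile(x)
        return total

    def window_area(lo, hi):
        x = np.arange(lo, hi + step / 2, step)
        return float(np.trapezoid(sum_profile(x), x))

    def fwhm(lo, hi):
        x = np.arange(lo, hi + step / 2, step)
        y = sum_profile(x)
        p = int(np.argmax(y))
        half = y[p] / 2.0
        left = x[:p][np.nonzero(y[:p] <= half)[0][-1]] if np.any(y[:p] <= half) else x[0]
        right = x[p:][np.nonzero(y[p:] <= half)[0][0]] if np.any(y[p:] <= half) else x[-1]
        return float(right - left)

    def value(at):
        return float(sum_profile(np.array([at]))[0])

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    b = BANDS
    nu1_area = window_area(b["nu1PO4"].lo, b["nu1PO4"].hi)
    return {
        "mineral_matrix": ratio(
            window_area(b["nu2PO4"].lo, b["nu2PO4"].hi),
            window_area(b["amideIII"].lo, b["amideIII"].hi),
        ),
        "carbonate_phosphate": ratio(
            window_area(b["nu1CO3"].lo, b["nu1CO3"].hi), nu1_area
        ),
        "crystallinity": 1.0 / fwhm(b["nu1PO4"].lo, b["nu1PO4"].hi)
        if nu1_area > 0
        else float("nan"),
        "collagen_maturity": ratio(value(1660.0), value(1690.0)),
        "pen_ratio": ratio(value(1495.0), value(1450.0)),
    }


def gen_raman_spectrum(
    truth: SpectrumTruth,
    step: float = 1.0,
    seed: int = 0,
    lo: float = 280.0,
    hi: float = 2000.0,
) -> tuple[RamanSpectrum, SpectrumTruth]:
    """Sample the forward model on a uniform axis spanning [lo, hi]."""
    if step > 2.0:
        raise ValueError("step must be <= 2 cm^-1")
    rng = np.random.default_rng(seed)
    x = np.arange(lo, hi + step / 2, step)
    y = truth.band_sum(x)
    if len(truth.baseline_coeffs):
        # evaluate on a shifted axis to keep polynomial coefficients tame
        y = y + np.polyval(truth.baseline_coeffs, (x - x[0]) / (x[-1] - x[0]))
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=x.shape)
    return RamanSpectrum(x, y, n_accumulations=1), truth
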