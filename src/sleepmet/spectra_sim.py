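"""Pseudo ¹H NMR plasma spectra for exercising the spectral branch.

Spectra are sums of Lorentzian lines on a descending 10.0 → −0.5 ppm axis
(16,384 points): the β-glucose anomeric doublet centred at 5.223 ppm, glucose
ring multiplets at 3.2–3.9 ppm, the lactate doublet (~1.33) and quartet
(~4.11), BCAA methyl doublets at 0.9–1.05 ppm, broad lipoprotein (LDL/VLDL
methyl/methylene) envelopes at 0.8–1.3 ppm and a residual water hump at
4.70 ppm, plus additive Gaussian noise. Spectra are phase-corrected and
baseline-flat by construction; an optional global ppm mis-calibration per
spectrum emulates referencing error, and an outlier plan can inflate the
glucose or lactate amplitudes of designated spectra.
"""

from __future__ import annotations

import numpy as np

from .nmr import GLUCOSE_ANOMERIC_PPM, Spectrum

PPM_MAX, PPM_MIN, N_POINTS = 10.0, -0.5, 16384

# (centre ppm, half-width ppm, relative amplitude) per resonance group
_J_DOUBLET = 0.0032  # half-splitting of the anomeric doublet (≈3.8 Hz at 600 MHz)
_LAC_SPLIT = 0.0058  # lactate CH3 doublet half-splitting (≈7 Hz)


def default_axis() -> np.ndarray:
    return np.linspace(PPM_MAX, PPM_MIN, N_POINTS)


def _lorentz(ppm: np.ndarray, centre: float, hw: float, amp: float) -> np.ndarray:
    return amp * hw**2 / ((ppm - centre) ** 2 + hw**2)


def _spectrum_profile(
    ppm: np.ndarray, glucose_amp: float, lactate_amp: float, rng: np.random.Generator | None
) -> np.ndarray:
    def v(base: float, sd: float = 0.08) -> float:
        return base * float(np.exp(rng.normal(0, sd))) if rng is not None else base

    y = np.zeros_like(ppm)
    # beta-glucose anomeric doublet at the reference position
    for s in (-_J_DOUBLET, _J_DOUBLET):
        y += _lorentz(ppm, GLUCOSE_ANOMERIC_PPM + s, 0.0015, glucose_amp)
    # glucose ring protons
    for c, a in ((3.25, 0.8), (3.42, 1.0), (3.55, 0.9), (3.73, 1.1), (3.85, 0.7)):
        y += _lorentz(ppm, c, 0.004, glucose_amp * a)
    # lactate doublet + quartet
    for s in (-_LAC_SPLIT, _LAC_SPLIT):
        y += _lorentz(ppm, 1.33 + s, 0.0015, lactate_amp)
    y += _lorentz(ppm, 4.11, 0.003, lactate_amp * 0.25)
    # BCAA methyl region
    for c, a in ((0.96, 0.20), (0.99, 0.22), (1.02, 0.18)):
        y += _lorentz(ppm, c, 0.0018, v(a))
    # broad lipoprotein envelopes (LDL/VLDL CH3 and CH2)
    y += _lorentz(ppm, 0.87, 0.05, v(0.6))
    y += _lorentz(ppm, 1.28, 0.06, v(0.9))
    # residual water
    y += _lorentz(ppm, 4.70, 0.02, v(0.5))
    return y


def default_outlier_plan(n: int) -> dict[int, tuple[str, float]]:
    """Four planted outliers: three high-glucose spectra and one high-lactate.

    The amplitude factors differ between the glucose outliers, as distinct
    hyperglycaemic animals would.
    """
    if n < 5:
        raise ValueError("need n >= 5 for the default outlier plan")
    return {
        0: ("glucose", 3.0),
        n // 3: ("glucose", 4.5),
        2 * n // 3: ("glucose", 6.0),
        n - 1: ("lactate", 5.0),
    }


def simulate_spectra(
    n: int,
    outlier_plan: dict[int, tuple[str, float] | str] | None = None,
    seed: int = 0,
    noise_sd: float = 0.002,
    miscal_sd: float = 0.0,
    outlier_factor: float = 4.0,
    amp_sd: float = 0.08,
) -> list[Spectrum]:
    """Simulate ``n`` plasma-like spectra.

    ``outlier_plan`` maps spectrum index → "glucose" | "lactate" (optionally a
    (kind, factor) tuple); those spectra get the respective amplitude
    multiplied by the factor (default ``outlier_factor``). ``miscal_sd`` is
    the sd (ppm) of a per-spectrum global axis shift.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    outlier_plan = outlier_plan or {}
    axis = default_axis()
    spectra = []
    for i in range(n):
        glc = 1.0 * float(np.exp(rng.normal(0, amp_sd)))
        lac = 0.5 * float(np.exp(rng.normal(0, amp_sd)))
        entry = outlier_plan.get(i)
        kind, factor = (entry, outlier_factor) if isinstance(entry, str) else (entry or (None, 1.0))
        if kind == "glucose":
            glc *= factor
        elif kind == "lactate":
            lac *= factor
        offset = rng.normal(0, miscal_sd) if miscal_sd > 0 else 0.0
        y = _spectrum_profile(axis - offset, glc, lac, rng if amp_sd > 0 else None)
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, size=axis.size)
        spectra.append(Spectrum(axis.copy(), y, ["simulated"], f"spec_{i:03d}"))
    return spectra
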