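"""¹H NMR spectral preprocessing: referencing, water excision, digitization
and PCA-based outlier removal.

Spectra are (ppm, intensity) pairs on a strictly decreasing ppm axis (NMR
convention). The processing order is: reference to the β-glucose anomeric
doublet at δ 5.223 → excise the water region (default 4.5–5.1 ppm) → linearly
interpolate all spectra onto a common grid → Pareto-scaled PCA with a
Hotelling T² limit (default 99%) to flag and remove outliers. Each step
appends to the spectrum's provenance list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chemometrics import fit_pca, pca_outlier_flag, scale_matrix

GLUCOSE_ANOMERIC_PPM = 5.223
GLUCOSE_BAND = (5.18, 5.27)
LACTATE_BAND = (1.315, 1.345)


class NmrError(ValueError):
    pass


@dataclass
class Spectrum:
    """A 1-D spectrum: strictly decreasing ppm axis, intensities, provenance."""

    ppm: np.ndarray
    intensity: np.ndarray
    provenance: list[str] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise NmrError("ppm and intensity must have equal length")
        if not (np.diff(self.ppm) < 0).all():
            raise NmrError("ppm axis must be strictly decreasing")

    def with_step(self, ppm: np.ndarray, intensity: np.ndarray, step: str) -> "Spectrum":
        return Spectrum(ppm, intensity, [*self.provenance, step], self.id)

    def grid_step(self) -> float:
        return float(np.median(-np.diff(self.ppm)))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame({"ppm": self.ppm, "intensity": self.intensity}).to_csv(path, index=False)


def read_spectrum(path: str | Path, spectrum_id: str = "") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), [], spectrum_id or Path(path).stem)


# ---------------------------------------------------------------------------
# referencing


def _doublet_centre(ppm: np.ndarray, intens: np.ndarray) -> float:
    """Centre of the dominant doublet (mean of the two highest close peaks)."""
    idx, props = find_peaks(intens, prominence=0.05 * intens.max())
    if len(idx) == 0:
        idx = np.array([int(np.argmax(intens))])
    order = idx[np.argsort(intens[idx])[::-1]]
    apex = ppm[order[0]]
    if len(order) > 1 and abs(ppm[order[1]] - apex) < 0.02:
        return float(0.5 * (apex + ppm[order[1]]))
    return float(apex)


def reference_to_glucose(
    spectrum: Spectrum,
    target_ppm: float = GLUCOSE_ANOMERIC_PPM,
    window: tuple[float, float] = (5.0, 5.5),
) -> Spectrum:
    """Shift the ppm axis so the anomeric doublet centre sits at the target.

    The doublet is searched in the given window; a peak must rise clearly
    above the noise floor (median + 5×MAD of the whole spectrum) or an error
    is raised.
    """
    lo, hi = min(window), max(window)
    sel = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not sel.any():
        raise NmrError("reference window outside spectrum range")
    seg_ppm, seg_int = spectrum.ppm[sel], spectrum.intensity[sel]
    noise = np.median(spectrum.intensity) + 5 * np.median(
        np.abs(spectrum.intensity - np.median(spectrum.intensity))
    )
    if seg_int.max() <= noise:
        raise NmrError("reference peak not found above noise floor")
    centre = _doublet_centre(seg_ppm, seg_int)
    shift = target_ppm - centre
    return spectrum.with_step(spectrum.ppm + shift, spectrum.intensity.copy(), f"reference(shift={shift:+.6f})")


# ---------------------------------------------------------------------------
# water excision


def excise_water(spectrum: Spectrum, lo_ppm: float = 4.5, hi_ppm: float = 5.1) -> Spectrum:
    """Remove axis points with lo ≤ ppm ≤ hi (default water region 4.5–5.1)."""
    if lo_ppm >= hi_ppm:
        raise NmrError("excision region must satisfy lo < hi")
    if lo_ppm <= GLUCOSE_ANOMERIC_PPM <= hi_ppm:
        raise NmrError("water region must not cover the 5.223 ppm reference")
    keep = (spectrum.ppm < lo_ppm) | (spectrum.ppm > hi_ppm)
    if not keep.any():
        raise NmrError("excision region covers the whole spectrum")
    return spectrum.with_step(
        spectrum.ppm[keep], spectrum.intensity[keep], f"excise_water({lo_ppm},{hi_ppm})"
    )


# ---------------------------------------------------------------------------
# digitization


def digitize(spectra: list[Spectrum], grid: np.ndarray) -> pd.DataFrame:
    """Linear interpolation of every spectrum onto a common (decreasing) grid.

    Returns a DataFrame with one row per spectrum, columns = grid ppm values.
    """
    grid = np.asarray(grid, dtype=float)
    if not (np.diff(grid) < 0).all():
        raise NmrError("grid must be strictly decreasing")
    rows = {}
    for k, sp in enumerate(spectra):
        if grid.max() > sp.ppm.max() + 1e-9 or grid.min() < sp.ppm.min() - 1e-9:
            raise NmrError(f"grid outside range of spectrum {sp.id or k}")
        # np.interp needs ascending x
        rows[sp.id or f"spec_{k}"] = np.interp(grid[::-1], sp.ppm[::-1], sp.intensity[::-1])[::-1]
    return pd.DataFrame(rows, index=grid).T


def common_grid(spectra: list[Spectrum]) -> np.ndarray:
    """The first spectrum's axis restricted to the range covered by all spectra."""
    lo = max(sp.ppm.min() for sp in spectra)
    hi = min(sp.ppm.max() for sp in spectra)
    if lo >= hi:
        raise NmrError("spectra have no overlapping ppm range")
    g = spectra[0].ppm
    return g[(g >= lo) & (g <= hi)]


# ---------------------------------------------------------------------------
# outlier removal


def remove_outliers_pca(
    matrix: pd.DataFrame, level: float = 0.99, n_comp: int = 4
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Pareto-scale → overview PCA → Hotelling T² flagging → drop flagged spectra.

    Removal is iterative: a group of similar outliers inflates its own score
    variance and can mask its members, so the model is refit after each
    removal round until no sample exceeds the limit. Returns (kept matrix,
    flagged ids, flagged id → dominant band annotation), where the annotation
    names the spectral region (glucose vs lactate band) contributing most to
    the flagged sample's deviation.
    """
    if len(matrix) < 5:
        raise NmrError("need >= 5 spectra for PCA outlier removal")
    kept = matrix
    flagged: list[str] = []
    while len(kept) >= 5:
        scaled = scale_matrix(kept.to_numpy(), "pareto")
        model = fit_pca(scaled.X, min(n_comp, len(kept) - 1))
        newly = pca_outlier_flag(model, list(kept.index), level)
        if not newly:
            break
        flagged.extend(newly)
        kept = kept.drop(index=newly)

    scaled_all = scale_matrix(matrix.to_numpy(), "pareto")
    ppm = matrix.columns.to_numpy(dtype=float)
    bands = {"glucose": GLUCOSE_BAND, "lactate": LACTATE_BAND}
    notes = {}
    for sid in flagged:
        dev = np.abs(scaled_all.X[list(matrix.index).index(sid)])
        scores = {}
        for name, (lo, hi) in bands.items():
            sel = (ppm >= lo) & (ppm <= hi)
            scores[name] = float(dev[sel].mean()) if sel.any() else 0.0
        notes[sid] = max(scores, key=scores.get)
    return kept, sorted(flagged), notes


# ---------------------------------------------------------------------------
# pipeline


def preprocess_spectra(
    spectra: list[Spectrum],
    water: tuple[float, float] = (4.5, 5.1),
    level: float = 0.99,
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Reference → excise → digitize → PCA outlier removal, in that order."""
    processed = [excise_water(reference_to_glucose(sp), *water) for sp in spectra]
    grid = common_grid(processed)
    mat = digitize(processed, grid)
    return remove_outliers_pca(mat, level)
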