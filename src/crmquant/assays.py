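"""Gel-zymogram densitometry and rheology power-law fits.

Two small quantifications that sit beside the imaging pipeline: per-band
cleared-pixel counts of a gelatin zymogram lane normalized by the cell
density used in the experiment, and a log-log power-law fit of an
oscillatory frequency sweep evaluated at 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ZymogramBand",
    "RheologySweep",
    "PowerLawFit",
    "quantify_zymogram",
    "fit_power_law",
    "suggest_zymogram_threshold",
]


@dataclass(frozen=True)
class ZymogramBand:
    """One proteolytic band: cleared-pixel area and its normalization.

    ``normalized_activity`` = pixel_area / cell_density (pixels·mL/cell).
    ``label`` is "MMP-9" (upper band), "MMP-2" (lower band) or "other";
    the assignment is positional (MMP-9 ≈ 92 kDa migrates above MMP-2 ≈
    72 kDa), not ladder-calibrated.
    """

    label: str
    pixel_area: int
    row_position: float
    cell_density: float
    normalized_activity: float


@dataclass(frozen=True)
class RheologySweep:
    """An oscillatory frequency sweep: frequencies (Hz) and storage moduli (Pa)."""

    frequencies: tuple[float, ...]
    moduli: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        g = np.asarray(self.moduli, dtype=float)
        if f.size != g.size:
            raise ValueError("frequencies and moduli must have equal length")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(g <= 0):
            raise ValueError("moduli must be positive")


@dataclass(frozen=True)
class PowerLawFit:
    """G(f) = prefactor x f^exponent, with the modulus evaluated at 10 Hz."""

    prefactor: float
    exponent: float
    modulus_at_10Hz: float
    r_squared: float


def suggest_zymogram_threshold(lane_image: np.ndarray) -> float:
    """Otsu suggestion for the cleared-band threshold (the choice is the
    user's; the applied value is always recorded in the output)."""
    return float(threshold_otsu(np.asarray(lane_image, dtype=float)))


def quantify_zymogram(
    lane_image: np.ndarray,
    threshold: float,
    cell_density: float,
    polarity: str = "clear_bands_low",
    min_band_pixels: int = 1,
    major_band_fraction: float = 0.25,
) -> list[ZymogramBand]:
    """Quantify proteolytic bands in one zymogram lane.

    Cleared (digested) regions are segmented by thresholding — polarity
    "clear_bands_low" selects pixels below the threshold (cleared bands in
    a stained gel are bright on film but dark in inverted scans; pick the
    polarity matching the scan) — then separated by connected-component
    labelling. Each band's activity is its pixel count divided by the cell
    density of the conditioned-media culture, so doubling the density
    exactly halves the activity.

    When exactly two major bands are present (area ≥ ``major_band_fraction``
    of the largest), the upper one is labelled MMP-9 and the lower MMP-2;
    any other configuration yields "other" labels with row positions
    reported. A lane with no cleared pixels is a valid zero-activity result.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    img = np.asarray(lane_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("lane_image must be a 2D grayscale array")
    if polarity == "clear_bands_low":
        cleared = img < threshold
    elif polarity == "clear_bands_high":
        cleared = img > threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not cleared.any():
        return []
    labels = label(cleared, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_band_pixels]
    if not props:
        return []
    areas = np.array([p.area for p in props])
    major = areas >= major_band_fraction * areas.max()
    props_sorted = sorted(props, key=lambda p: p.centroid[0])  # top first
    bands: list[ZymogramBand] = []
    two_major = int(major.sum()) == 2
    major_ids = {p.label for p, m in zip(props, major) if m}
    majors_in_order = [p for p in props_sorted if p.label in major_ids]
    for p in props_sorted:
        if two_major and p.label in major_ids:
            name = "MMP-9" if p is majors_in_order[0] else "MMP-2"
        else:
            name = "other"
        bands.append(
            ZymogramBand(
                label=name,
                pixel_area=int(p.area),
                row_position=float(p.centroid[0]),
                cell_density=float(cell_density),
                normalized_activity=float(p.area) / float(cell_density),
            )
        )
    return bands


def fit_power_law(sweep: RheologySweep) -> PowerLawFit:
    """Fit G(f) = a·f^b by least squares on log G vs log f.

    Exact on noiseless power-law data; ``modulus_at_10Hz`` is the fitted
    line evaluated at 10 Hz, so the identity a·10^b holds to machine
    precision by construction.
    """
    f = np.asarray(sweep.frequencies, dtype=float)
    g = np.asarray(sweep.moduli, dtype=float)
    if f.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    lx, ly = np.log(f), np.log(g)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = intercept + slope * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    a = float(np.exp(intercept))
    b = float(slope)
    return PowerLawFit(
        prefactor=a,
        exponent=b,
        modulus_at_10Hz=a * 10.0**b,
        r_squared=r2,
    )
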