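"""2D peak detection on TIC images.

Peaks are found on the background-subtracted TIC image by watershed
segmentation seeded from local maxima: shoulder maxima are merged by h-maxima
suppression (default h = 3 × noise level), each surviving seed grows a
watershed basin (its footprint), and a peak is retained iff its footprint
volume passes the absolute TIC-count gate and its apex passes the S/N gate
(apex TIC / noise level).  The peak's mass spectrum is the single spectrum at
the apex pixel of the raw data cube ("largest data point within the peak"),
base-peak normalized to 999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .gc2d import Chromatogram2D, TICImage
from .preprocess import NoiseEstimate
from .specmatch import normalize_spectrum


@dataclass
class Peak2D:
    """A detected 2D peak.

    ``rt1`` in minutes (¹D), ``rt2`` in seconds (²D); ``volume`` is the TIC
    summed over the watershed footprint; ``snr`` is apex TIC over the robust
    noise level; ``footprint`` holds (modulation, sample) pixel indices.
    """

    rt1: float
    rt2: float
    apex_pixel: tuple[int, int]
    volume: float
    snr: float
    spectrum: np.ndarray | None = None
    footprint: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    @property
    def apex_height(self) -> float:
        return self.snr  # apex/noise; kept as a ratio


def detect_peaks(image: TICImage, min_counts: float, min_snr: float,
                 noise: NoiseEstimate, h: float | None = None,
                 mask_level: float | None = None) -> list[Peak2D]:
    """Detect 2D peaks on a background-subtracted TIC image.

    Parameters
    ----------
    min_counts : absolute TIC volume gate (counts).
    min_snr : apex-to-noise gate.
    noise : background noise estimate for the image.
    h : h-maxima suppression depth; default ``3 × noise.level``.
    mask_level : pixels below this level are excluded from footprints;
        default ``noise.level``.

    Returns peaks sorted by volume, descending.  Equal-height apex ties break
    toward the lower ¹D index, then the lower ²D index (C-order argmax).
    """
    img = np.asarray(image.image, dtype=np.float64)
    level = noise.level
    if h is None:
        h = 3.0 * level if level > 0 else max(1e-9, 1e-6 * max(img.max(), 1.0))
    if mask_level is None:
        mask_level = level
    seeds = h_maxima(img, h)
    markers, n_seeds = ndimage.label(seeds)
    if n_seeds == 0:
        return []
    mask = img > mask_level
    labels = watershed(-img, markers=markers, mask=mask)
    peaks: list[Peak2D] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        sub = img[sl]
        volume = float(sub[region].sum())
        # apex: first (C-order) occurrence of the maximum inside the region
        masked = np.where(region, sub, -np.inf)
        flat = int(np.argmax(masked))
        ai, aj = np.unravel_index(flat, masked.shape)
        ai += sl[0].start
        aj += sl[1].start
        apex = img[ai, aj]
        snr = float(apex / level) if level > 0 else np.inf
        if volume < min_counts or snr < min_snr:
            continue
        fp = np.argwhere(labels == lab)
        rt1, rt2 = image.pixel_to_rt(ai, aj)
        peaks.append(Peak2D(
            rt1=float(rt1), rt2=float(rt2), apex_pixel=(int(ai), int(aj)),
            volume=volume, snr=snr, footprint=fp))
    peaks.sort(key=lambda p: (-p.volume, p.apex_pixel))
    return peaks


def peak_spectrum(cube: Chromatogram2D, peak: Peak2D) -> np.ndarray:
    """Mass spectrum at the peak's apex pixel, base peak normalized to 999."""
    i, j = peak.apex_pixel
    n_mod, p, _ = cube.cube.shape
    if not (0 <= i < n_mod and 0 <= j < p):
        raise ValueError(f"apex pixel {peak.apex_pixel} outside cube bounds")
    inten = np.asarray(cube.cube[i, j, :], dtype=float)
    nz = inten > 0
    if not nz.any():
        raise ValueError("apex spectrum is empty (all-zero data point)")
    spec = np.column_stack([np.asarray(cube.mz_axis, float)[nz], inten[nz]])
    return normalize_spectrum(spec)


def attach_spectra(cube: Chromatogram2D, peaks: list[Peak2D]) -> list[Peak2D]:
    """Fill in the apex spectrum of every peak from the raw cube (in place)."""
    for pk in peaks:
        pk.spectrum = peak_spectrum(cube, pk)
    return peaks


def integrate_volume(image: TICImage, footprint: np.ndarray) -> float:
    """Exact TIC sum over a footprint given as (n, 2) pixel indices."""
    fp = np.asarray(footprint)
    if fp.size == 0:
        raise ValueError("footprint is empty")
    img = np.asarray(image.image)
    return float(img[fp[:, 0], fp[:, 1]].sum(dtype=np.float64))
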