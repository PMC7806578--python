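"""Retention-index identification and class-composite comparison.

Linear (temperature-programmed) retention indices I^T are computed from the
¹D apex times of an n-alkane C7–C30 calibration run by van den Dool–Kratz
interpolation.  Putative identification of a peak requires three simultaneous
gates against the library: DMF ≥ 900, RMF ≥ 950 and |I^T(exp) − I^T(lib)| ≤
10 units (all boundaries inclusive).

Class comparison accumulates aligned TIC images into composite class images
and renders their misalignment-tolerant ("fuzzy") per-pixel log2 ratio after
each image is normalized by its own total response; positive values mark
features stronger in the analyzed class, negative ones the reference class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gc2d import TICImage
from .fingerprint import Transform, build_composite
from .peaks import Peak2D
from .specmatch import match_factors
from .synth import SpectralLibrary


@dataclass
class RICalibration:
    """Strictly increasing (carbon number, ¹D time) alkane calibration."""

    carbon_numbers: np.ndarray
    rt1_minutes: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_numbers = np.asarray(self.carbon_numbers, dtype=int)
        self.rt1_minutes = np.asarray(self.rt1_minutes, dtype=float)
        if len(self.carbon_numbers) < 2:
            raise ValueError("need at least 2 alkanes to calibrate")
        if len(self.carbon_numbers) != len(self.rt1_minutes):
            raise ValueError("carbon numbers and times must align")
        if len(np.unique(self.carbon_numbers)) != len(self.carbon_numbers):
            raise ValueError("duplicate carbon numbers")
        if not np.all(np.diff(self.carbon_numbers) > 0):
            raise ValueError("carbon numbers must be sorted increasing")
        if not np.all(np.diff(self.rt1_minutes) > 0):
            raise ValueError("alkane retention times must be strictly increasing")


def retention_index(rt1: float, calib: RICalibration) -> float:
    """Van den Dool–Kratz linear retention index of a ¹D retention time.

    ``I^T = 100·n + 100·(rt − t_n)/(t_{n+1} − t_n)`` for the bracketing
    alkanes n, n+1; outside the calibrated range the edge segment is
    extrapolated.
    """
    t = calib.rt1_minutes
    c = calib.carbon_numbers.astype(float)
    k = int(np.clip(np.searchsorted(t, rt1) - 1, 0, len(t) - 2))
    frac = (rt1 - t[k]) / (t[k + 1] - t[k])
    return float(100.0 * (c[k] + (c[k + 1] - c[k]) * frac))


@dataclass
class Identification:
    peak: Peak2D
    compound: str
    dmf: int
    rmf: int
    ri_exp: float
    ri_lib: float
    accepted: bool


def identify(peak: Peak2D, ri_exp: float, library: SpectralLibrary,
             min_dmf: int = 900, min_rmf: int = 950, ri_tol: float = 10.0,
             channel: str = "70eV",
             mz_range: tuple[int, int] | None = None) -> list[Identification]:
    """Rank library candidates for a peak; flag those passing all three gates.

    Candidates are ordered by DMF descending; ``accepted`` requires
    DMF ≥ ``min_dmf``, RMF ≥ ``min_rmf`` and |ΔI^T| ≤ ``ri_tol``.
    ``mz_range`` clips library spectra to the instrument's acquisition range
    before scoring, so fragments the detector never saw cannot penalize the
    match.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if peak.spectrum is None:
        raise ValueError("peak carries no spectrum")
    results = []
    for entry in library:
        ref = entry.spectrum(channel)
        if mz_range is not None:
            keep = (ref[:, 0] >= mz_range[0]) & (ref[:, 0] <= mz_range[1])
            if not keep.any():
                continue
            ref = ref[keep]
        dmf, rmf = match_factors(peak.spectrum, ref)
        accepted = (dmf >= min_dmf and rmf >= min_rmf
                    and abs(ri_exp - entry.ri) <= ri_tol)
        results.append(Identification(
            peak=peak, compound=entry.name, dmf=dmf, rmf=rmf,
            ri_exp=ri_exp, ri_lib=entry.ri, accepted=accepted))
    results.sort(key=lambda r: -r.dmf)
    return results


def class_composite(runs_of_class: list[TICImage], transforms: list[Transform],
                    mode: str = "sum") -> TICImage:
    """Aligned accumulation of one class's runs (sum or mean)."""
    if len(runs_of_class) == 0:
        raise ValueError("class has no runs")
    return build_composite(runs_of_class, transforms, mode=mode)


@dataclass
class RatioImage:
    """Signed per-pixel log2 ratio in template space (NaN = masked)."""

    log2_ratio: np.ndarray
    modulation_period: float
    acquisition_rate: float


def fuzzy_ratio(analyzed: TICImage, reference: TICImage,
                tolerance_window: int = 3, floor: float = 0.0) -> RatioImage:
    """Misalignment-tolerant log2 ratio of two total-normalized images.

    Both images are divided by their own total response, so a global scale
    difference cancels.  Each is then dilated with a ``tolerance_window`` ×
    ``tolerance_window`` maximum filter before taking the per-pixel quotient,
    absorbing residual misalignment up to half the window.  Pixels where
    either raw windowed maximum falls below ``floor`` counts are masked
    (NaN).  Swapping analyzed and reference negates the image exactly.
    """
    a = np.asarray(analyzed.image, dtype=np.float64)
    r = np.asarray(reference.image, dtype=np.float64)
    if a.shape != r.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {r.shape}")
    tot_a, tot_r = a.sum(), r.sum()
    if tot_a <= 0 or tot_r <= 0:
        raise ValueError("image totals must be > 0")
    size = int(tolerance_window)
    a_max = ndimage.maximum_filter(a, size=size)
    r_max = ndimage.maximum_filter(r, size=size)
    masked = (a_max < floor) | (r_max < floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((a_max / tot_a) / (r_max / tot_r))
    ratio[masked] = np.nan
    ratio[~np.isfinite(ratio) & ~np.isnan(ratio)] = np.nan
    return RatioImage(log2_ratio=ratio,
                      modulation_period=analyzed.modulation_period,
                      acquisition_rate=analyzed.acquisition_rate)


def render_ratio(ratio: RatioImage, path, clip: float = 3.0) -> None:
    """Save a red/green diverging rendering of a fuzzy-ratio image.

    Green marks features stronger in the analyzed class, red those stronger
    in the reference class; masked pixels are left neutral.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.clip(np.nan_to_num(ratio.log2_ratio, nan=0.0), -clip, clip)
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(img.T, origin="lower", aspect="auto", cmap="RdYlGn",
                   vmin=-clip, vmax=clip)
    ax.set_xlabel("1D retention (modulation index)")
    ax.set_ylabel("2D retention (sample index)")
    fig.colorbar(im, ax=ax, label="log2 ratio (analyzed / reference)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
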