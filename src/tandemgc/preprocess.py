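"""Background subtraction, noise estimation, and tandem-channel fusion.

Background removal follows the rolling-ball (Sternberg) construction: the
background under the TIC image is the grey-scale opening with a ball
structuring element whose radius greatly exceeds the chromatographic peak
width, so genuine 2D peaks survive while smooth baseline (column bleed) is
removed.  Noise is the robust scale (MAD × 1.4826) of background pixels and
feeds the S/N → absolute-counts threshold mapping used for peak detection
gates.  Channel fusion is the exact voxel-wise sum of the 12 eV and 70 eV
data streams of a run — no rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.morphology import disk

from .gc2d import Chromatogram2D, TICImage


@dataclass
class NoiseEstimate:
    """Robust background noise level (counts) and how it was obtained."""

    level: float
    method: str = "mad"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def subtract_background(image: TICImage, ball_radius: int,
                        smooth_sigma: float = 2.0) -> TICImage:
    """Subtract the rolling-ball background from a TIC image.

    The background is the grey-scale opening of the image with a disk of
    ``ball_radius`` pixels — a rolling ball whose intensity radius is taken
    much larger than any peak height, appropriate for TIC scales (10³–10⁶
    counts) far exceeding the image's spatial extent.  The image is lightly
    Gaussian-smoothed (``smooth_sigma`` pixels) before rolling so that noise
    pits do not drag the ball down, edges are handled by replication, and the
    background is capped at the original image.  The returned image is
    ``input − background`` clipped at zero; the background is everywhere ≤
    the input, so peak volumes are preserved for features narrower than the
    ball.
    """
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    if ball_radius >= max(image.shape):
        raise ValueError(
            f"ball_radius {ball_radius} exceeds image extent {image.shape}")
    img = np.asarray(image.image, dtype=np.float64)
    base = gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    # pad by 2r with edge replication: the opening's two passes otherwise
    # both clip against the image border and leave a slope × radius residual
    pad = 2 * ball_radius
    padded = np.pad(base, pad, mode="edge")
    opened = ndimage.grey_opening(padded, footprint=disk(ball_radius))
    opened = opened[pad:-pad, pad:-pad]
    background = np.minimum(opened, img)
    residual = np.clip(img - background, 0.0, None)
    return image.copy_with(residual)


def estimate_noise(image: TICImage, exclusion_mask: np.ndarray | None = None) -> NoiseEstimate:
    """Robust σ of background pixels: ``1.4826 × MAD`` about the median.

    ``exclusion_mask`` marks pixels to ignore (True = excluded, e.g. peak
    footprints); at least 100 background pixels must remain.
    """
    img = np.asarray(image.image, dtype=np.float64)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("exclusion mask shape does not match image")
        values = img[~mask]
    else:
        values = img.ravel()
    if values.size == 0:
        raise ValueError("all pixels masked; no background left to estimate")
    if values.size < 100:
        raise ValueError(
            f"only {values.size} background pixels available; need >= 100")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return NoiseEstimate(level=float(1.4826 * mad), method="mad")


def snr_threshold_to_counts(snr: float, noise: NoiseEstimate) -> float:
    """Map an S/N gate to an absolute TIC-count threshold (snr × noise)."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return snr * noise.level


def fuse_channels(chan70: Chromatogram2D, chan12: Chromatogram2D) -> Chromatogram2D:
    """Voxel-wise sum of the parallel 70 eV and 12 eV data streams of a run.

    Grids must be identical; the result is tagged ``fused`` and its total ion
    count is exactly the sum of the channel totals.
    """
    if chan70.cube.shape != chan12.cube.shape:
        raise ValueError(
            f"cube shapes differ: {chan70.cube.shape} vs {chan12.cube.shape}")
    if not np.array_equal(chan70.mz_axis, chan12.mz_axis):
        raise ValueError("m/z axes differ between channels")
    if chan70.modulation_period != chan12.modulation_period:
        raise ValueError("modulation periods differ between channels")
    if chan70.acquisition_rate != chan12.acquisition_rate:
        raise ValueError("acquisition rates differ between channels")
    if chan70.run_id != chan12.run_id:
        raise ValueError(
            f"run ids differ: {chan70.run_id!r} vs {chan12.run_id!r}")
    fused = chan70.cube.astype(np.float64) + chan12.cube.astype(np.float64)
    return Chromatogram2D(
        cube=fused,
        mz_axis=chan70.mz_axis,
        modulation_period=chan70.modulation_period,
        acquisition_rate=chan70.acquisition_rate,
        channel="fused",
        run_id=chan70.run_id,
    )
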