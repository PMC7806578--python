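"""Template-based untargeted fingerprinting across chromatograms.

The cross-sample alignment object is a *template*: a set of registration
("reliable") 2D peaks with expected retention coordinates and reference
spectra, later augmented with untargeted *peak regions* (watershed footprints
delineated on the composite chromatogram).  Matching a template against a
run's peak list is constrained twice — candidates must fall inside a
retention-time window, and their apex spectra must clear both the direct and
reverse match-factor gates (default 750/750) — then resolved one-to-one,
greedily in descending DMF order.

Reliable peaks are template entries positively matched in more than half of
the chromatograms of the set (25 of 48 for the full design); they anchor a
per-run affine retention transform.  Aligned TIC images are resampled into
template space and summed into a composite, on which peak regions are
delineated and then quantified in every run, yielding the runs × features
matrix that downstream statistics consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gc2d import TICImage, SECONDS_PER_MINUTE
from .peaks import Peak2D, detect_peaks
from .preprocess import NoiseEstimate, estimate_noise
from .specmatch import match_factors


@dataclass
class TemplateEntry:
    id: str
    expected_rt1: float            # min
    expected_rt2: float            # s
    spectrum: np.ndarray | None = None
    kind: str = "reliable_peak"    # or "peak_region"
    region_pixels: np.ndarray | None = None  # (n, 2) template-space pixels

    def __post_init__(self) -> None:
        if self.kind == "peak_region" and self.region_pixels is None:
            raise ValueError("peak_region entries must carry a footprint")
        if self.kind == "reliable_peak" and self.spectrum is None:
            raise ValueError("reliable_peak entries must carry a spectrum")


@dataclass
class Transform:
    """Per-dimension affine map from template retention time to run retention
    time: ``run_rt1 = a1·rt1 + b1`` (min), ``run_rt2 = a2·rt2 + b2`` (s)."""

    a1: float = 1.0
    b1: float = 0.0
    a2: float = 1.0
    b2: float = 0.0
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 == 0 or self.a2 == 0:
            raise ValueError("transform must have nonzero scale in both dimensions")

    def apply(self, rt1, rt2):
        return self.a1 * np.asarray(rt1) + self.b1, self.a2 * np.asarray(rt2) + self.b2

    def invert(self) -> "Transform":
        return Transform(1.0 / self.a1, -self.b1 / self.a1,
                         1.0 / self.a2, -self.b2 / self.a2, self.rms_residual)


@dataclass
class Match:
    entry: TemplateEntry
    peak: Peak2D
    dmf: int
    rmf: int


@dataclass
class FeatureMatrix:
    """Runs × features table of TIC volumes with group labels."""

    volumes: pd.DataFrame           # index run_id, columns feature ids
    groups: pd.Series               # index run_id → {QC, MHO, MUO}
    channel: str = "fused"

    def __post_init__(self) -> None:
        if (self.volumes.values < 0).any():
            raise ValueError("feature volumes must be non-negative")


def template_from_peaks(peaks: list[Peak2D], prefix: str = "P") -> list[TemplateEntry]:
    """Seed a template from a reference run's detected peaks (with spectra)."""
    entries = []
    for k, pk in enumerate(peaks):
        if pk.spectrum is None:
            raise ValueError("peaks must carry apex spectra to seed a template")
        entries.append(TemplateEntry(
            id=f"{prefix}{k:03d}", expected_rt1=pk.rt1, expected_rt2=pk.rt2,
            spectrum=pk.spectrum, kind="reliable_peak"))
    return entries


def match_template(template: list[TemplateEntry], peaks: list[Peak2D],
                   window_1d: float, window_2d: float,
                   min_dmf: int = 750, min_rmf: int = 750,
                   transform: Transform | None = None) -> list[Match]:
    """One-to-one template ↔ peak matching under RT and spectral gates.

    ``window_1d`` (min) and ``window_2d`` (s) bound the candidate search
    around each entry's (optionally transformed) expected position; accepted
    candidates need DMF ≥ ``min_dmf`` and RMF ≥ ``min_rmf`` between the peak
    (query) and entry (reference) spectra.  Assignment is greedy in
    descending DMF; ties break toward the nearest Euclidean RT distance.
    """
    if not (0 <= min_dmf <= 999 and 0 <= min_rmf <= 999):
        raise ValueError("match-factor gates must lie in [0, 999]")
    if window_1d <= 0 or window_2d <= 0:
        raise ValueError("retention windows must be > 0")
    candidates = []
    for entry in template:
        if entry.spectrum is None:
            continue
        e1, e2 = entry.expected_rt1, entry.expected_rt2
        if transform is not None:
            e1, e2 = transform.apply(e1, e2)
        for pk in peaks:
            if abs(pk.rt1 - e1) > window_1d or abs(pk.rt2 - e2) > window_2d:
                continue
            if pk.spectrum is None:
                continue
            dmf, rmf = match_factors(pk.spectrum, entry.spectrum)
            if dmf < min_dmf or rmf < min_rmf:
                continue
            dist = np.hypot((pk.rt1 - e1) * SECONDS_PER_MINUTE, pk.rt2 - e2)
            candidates.append((dmf, dist, entry, pk, rmf))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used_entries: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[Match] = []
    for dmf, _dist, entry, pk, rmf in candidates:
        if id(entry) in used_entries or id(pk) in used_peaks:
            continue
        used_entries.add(id(entry))
        used_peaks.add(id(pk))
        matches.append(Match(entry, pk, dmf, rmf))
    return matches


def reliable_threshold(n_runs: int) -> int:
    """Minimum match count for reliability: more than half the runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return n_runs // 2 + 1


def select_reliable(match_counts: dict[str, int], n_runs: int) -> list[str]:
    """Entry ids matched in more than half of the chromatograms."""
    thr = reliable_threshold(n_runs)
    return [eid for eid, c in match_counts.items() if c >= thr]


def fit_transform(matched_pairs) -> Transform:
    """Least-squares per-dimension affine fit from (template RT, run RT) pairs.

    ``matched_pairs`` is an iterable of ((rt1_t, rt2_t), (rt1_r, rt2_r)).
    Requires ≥ 3 pairs with spread in both template dimensions.
    """
    pairs = list(matched_pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched pairs to fit a transform, got {len(pairs)}")
    t = np.array([p[0] for p in pairs], dtype=float)
    r = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(t[:, 0]) <= 0 or np.ptp(t[:, 1]) <= 0:
        raise ValueError("matched pairs must span both retention dimensions")
    a1, b1 = np.polyfit(t[:, 0], r[:, 0], 1)
    a2, b2 = np.polyfit(t[:, 1], r[:, 1], 1)
    res1 = r[:, 0] - (a1 * t[:, 0] + b1)
    res2 = r[:, 1] - (a2 * t[:, 1] + b2)
    rms = float(np.sqrt(np.mean(res1**2 * SECONDS_PER_MINUTE**2 + res2**2)))
    return Transform(float(a1), float(b1), float(a2), float(b2), rms)


def _warp_to_template(image: TICImage, transform: Transform) -> np.ndarray:
    """Resample a run image into template space (bilinear).

    For every template pixel the transform gives the corresponding run
    retention time; the run image is sampled there, so summing warped images
    accumulates aligned detector events.
    """
    n1, n2 = image.shape
    rt1 = np.arange(n1) * image.modulation_period / SECONDS_PER_MINUTE
    rt2 = np.arange(n2) / image.acquisition_rate
    run_rt1, run_rt2 = transform.apply(rt1, rt2)
    rows = run_rt1 * SECONDS_PER_MINUTE / image.modulation_period
    cols = run_rt2 * image.acquisition_rate
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(np.asarray(image.image, float),
                                   [grid_r, grid_c], order=1, mode="constant",
                                   cval=0.0)


def build_composite(runs: list[TICImage], transforms: list[Transform],
                    mode: str = "sum") -> TICImage:
    """Accumulate aligned run images in template space (sum or mean)."""
    if len(runs) == 0:
        raise ValueError("need at least one run to build a composite")
    if len(runs) != len(transforms):
        raise ValueError("one transform per run required")
    shape = runs[0].shape
    for im in runs[1:]:
        if im.shape != shape:
            raise ValueError(f"grid mismatch: {im.shape} vs {shape}")
    acc = np.zeros(shape, dtype=np.float64)
    for im, tr in zip(runs, transforms):
        acc += _warp_to_template(im, tr)
    if mode == "mean":
        acc /= len(runs)
    elif mode != "sum":
        raise ValueError("mode must be 'sum' or 'mean'")
    out = runs[0].copy_with(acc)
    out.run_id = "composite"
    return out


def delineate_regions(composite: TICImage, min_counts: float,
                      min_snr: float = 0.0,
                      noise: NoiseEstimate | None = None) -> list[TemplateEntry]:
    """Detect peaks on the composite; footprints become template peak regions."""
    if noise is None:
        noise = estimate_noise(composite)
    pks = detect_peaks(composite, min_counts=min_counts, min_snr=min_snr, noise=noise)
    return [
        TemplateEntry(id=f"R{k:03d}", expected_rt1=pk.rt1, expected_rt2=pk.rt2,
                      kind="peak_region", region_pixels=pk.footprint)
        for k, pk in enumerate(pks)
    ]


def quantify_features(runs: list[TICImage], regions: list[TemplateEntry],
                      transforms: list[Transform], run_ids: list[str],
                      groups: list[str], channel: str = "fused") -> FeatureMatrix:
    """Integrate every template peak region in every aligned run.

    Each run image is warped into template space through its fitted transform
    and the region footprints are summed there, so one region maps onto the
    same chemical feature in every run.  Regions falling entirely outside a
    run's image get volume 0 with a warning.
    """
    if len(runs) != len(transforms) or len(runs) != len(run_ids):
        raise ValueError("runs, transforms and run_ids must align")
    cols = [r.id for r in regions]
    data = np.zeros((len(runs), len(cols)))
    n1, n2 = runs[0].shape if runs else (0, 0)
    for ri, (im, tr) in enumerate(zip(runs, transforms)):
        warped = _warp_to_template(im, tr)
        for ci, region in enumerate(regions):
            fp = region.region_pixels
            inside = (fp[:, 0] >= 0) & (fp[:, 0] < n1) & (fp[:, 1] >= 0) & (fp[:, 1] < n2)
            if not inside.any():
                warnings.warn(
                    f"region {region.id} maps outside run {run_ids[ri]}; volume 0")
                continue
            data[ri, ci] = warped[fp[inside, 0], fp[inside, 1]].sum()
    volumes = pd.DataFrame(data, index=pd.Index(run_ids, name="run_id"), columns=cols)
    return FeatureMatrix(volumes=volumes,
                         groups=pd.Series(list(groups), index=volumes.index),
                         channel=channel)


@dataclass
class FingerprintResult:
    template: list[TemplateEntry]          # reliable peaks (post-selection)
    regions: list[TemplateEntry]
    transforms: dict[str, Transform]
    composite: TICImage
    features: FeatureMatrix
    match_counts: dict[str, int]
    reference_run: str


def align_and_quantify(images: dict[str, TICImage], peak_lists: dict[str, list[Peak2D]],
                       groups: dict[str, str], min_counts: float,
                       window_1d: float = 0.125, window_2d: float = 0.15,
                       min_dmf: int = 750, min_rmf: int = 750,
                       channel: str = "fused",
                       region_min_counts: float | None = None,
                       region_min_snr: float = 100.0) -> FingerprintResult:
    """Full fingerprinting pass over a set of runs.

    Seeds the template from the run with the highest total TIC, matches every
    run (match → fit transform → re-match once), keeps entries matched in
    more than half the runs as reliable peaks, builds the aligned composite,
    delineates untargeted peak regions at ``region_min_counts`` (default
    ``min_counts × n_runs``, i.e. the per-run gate scaled to the summed
    composite) and quantifies them across runs.
    """
    run_ids = list(images)
    ref = max(run_ids, key=lambda rid: float(np.sum(images[rid].image)))
    template = template_from_peaks(peak_lists[ref])

    def match_all(entries, transforms=None):
        counts = {e.id: 0 for e in entries}
        per_run = {}
        for rid in run_ids:
            tr = None if transforms is None else transforms.get(rid)
            ms = match_template(entries, peak_lists[rid], window_1d, window_2d,
                                min_dmf, min_rmf, transform=tr)
            per_run[rid] = ms
            for m in ms:
                counts[m.entry.id] += 1
        return counts, per_run

    counts, per_run = match_all(template)
    reliable_ids = set(select_reliable(counts, len(run_ids)))
    reliable = [e for e in template if e.id in reliable_ids]

    def fit_all(per_run_matches):
        transforms = {}
        for rid in run_ids:
            pairs = [((m.entry.expected_rt1, m.entry.expected_rt2),
                      (m.peak.rt1, m.peak.rt2))
                     for m in per_run_matches[rid] if m.entry.id in reliable_ids]
            try:
                transforms[rid] = fit_transform(pairs)
            except ValueError:
                transforms[rid] = Transform()  # fall back to identity
        return transforms

    transforms = fit_all(per_run)
    # one refinement pass: re-match with the fitted transforms, re-fit
    counts, per_run = match_all(reliable, transforms)
    reliable_ids = set(select_reliable(counts, len(run_ids)))
    reliable = [e for e in reliable if e.id in reliable_ids]
    transforms = fit_all(per_run)

    images_list = [images[rid] for rid in run_ids]
    # _warp_to_template samples the run at transform(template_rt); the fitted
    # template→run transform is exactly what sampling needs
    tr_for_warp = [transforms[rid] for rid in run_ids]
    composite = build_composite(images_list, tr_for_warp)
    if region_min_counts is None:
        region_min_counts = min_counts * len(run_ids)
    regions = delineate_regions(composite, min_counts=region_min_counts,
                                min_snr=region_min_snr)
    features = quantify_features(images_list, regions, tr_for_warp, run_ids,
                                 [groups[rid] for rid in run_ids], channel=channel)
    return FingerprintResult(
        template=reliable, regions=regions, transforms=transforms,
        composite=composite, features=features, match_counts=counts,
        reference_run=ref)
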