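"""Synthetic dual-energy GC×GC-TOF MS run generation with known ground truth.

The generator emulates a tandem-ionization saliva-fingerprinting study design:
4 QC + 3 MHO + 5 MUO subjects × 2 process replicates × 2 analytical replicates
(48 runs), each run acquired as two parallel ionization channels.  The 70 eV
channel carries classic electron-ionization spectra dominated by low-m/z
trimethylsilyl (TMS) fragments (73, 147, ...); the soft 12 eV channel
re-weights intensity toward high-m/z, structurally diagnostic fragments and
responds roughly one order of magnitude lower in TIC.

Each compound elutes as a 2D Gaussian blob: its ¹D position is set by its
linear retention index through an n-alkane (C7–C30) time grid derived from the
oven program, its ²D position by a per-compound elution time within the
modulation period.  Retention times are jittered run-to-run with configurable
% RSDs (defaults 0.20% in ¹D, 1.90% in ²D), shot noise is Poisson on blob
counts, and the background is a monotone column-bleed ramp carrying a bleed
mass spectrum plus Gaussian noise.

MUO (metabolically unhealthy obese) subjects scale selected compound
abundances by configured MUO:MHO ratios; with the ``% Diff`` convention
``(mean_MUO − mean_MHO)/mean_MHO × 100`` a reported +325.2% difference maps to
the ratio 4.252.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gc2d import Chromatogram2D, SECONDS_PER_MINUTE

GROUPS = ("QC", "MHO", "MUO")

ALKANE_CARBONS = tuple(range(7, 31))  # n-C7 .. n-C30

# Common TMS-derivative low-energy fragments (units Da, nominal mass).
_TMS_FRAGMENTS = (73, 75, 103, 117, 129, 133, 147, 155, 169, 189, 191, 204, 217)

# Curated subset of discriminant saliva metabolites: name, retention index,
# high-m/z diagnostic fragments (prominent at 12 eV), ²D time (s) and the
# MUO:MHO abundance ratio implied by the reported % difference.
NAMED_COMPOUNDS: tuple[tuple, ...] = (
    ("D-(+)-glucuronic acid gamma-lactone", 1923, (217, 246, 291, 333), 1.70, 4.252),
    ("urea", 1192, (99, 147, 171, 189), 2.98, 1.990),
    ("2-deoxy-D-ribose", 1589, (172, 205, 245, 259), 1.62, 1.878),
    ("N-acetylneuraminic acid methyl ester", 2270, (205, 298, 317, 375), 2.38, 1.772),
    ("5-aminovaleric acid", 1624, (174, 218, 232, 259), 1.84, 1.753),
    ("N-acetyl-D-glucosamine", 2052, (202, 319, 333), 2.24, 1.539),
    ("3-methyl-2-oxobutanoic acid", 1052, (89, 143, 173, 188), 1.76, 1.527),
    ("sucrose", 2678, (217, 271, 361, 437), 1.70, 1.409),
    ("citric acid", 1836, (273, 347, 363, 375), 1.84, 1.108),
    ("D-fructose", 1863, (217, 263, 307, 364), 1.60, 1.130),
    ("D-glucose", 1885, (205, 229, 319, 364), 1.64, 0.956),
    ("pyroglutamic acid", 1510, (156, 230, 258, 273), 2.42, 0.822),
    ("serine", 1367, (204, 218, 278, 306), 1.68, 0.406),
    ("D-sorbitol", 1920, (205, 319, 345, 421), 1.18, 0.281),
    ("D-lactose", 2604, (204, 217, 361, 451), 2.22, 0.125),
)


@dataclass
class LibraryEntry:
    """One library compound with dual-energy reference spectra.

    Spectra are (n, 2) arrays of (m/z [Da], relative intensity 0–999, base
    peak = 999).  ``response_70``/``response_12`` are the expected TIC blob
    volumes (counts) at unit abundance for the two ionization channels.
    """

    name: str
    ri: float
    spectrum_70: np.ndarray
    spectrum_12: np.ndarray
    response_70: float
    response_12: float
    two_d_time: float

    def spectrum(self, channel: str) -> np.ndarray:
        if channel == "70eV":
            return self.spectrum_70
        if channel == "12eV":
            return self.spectrum_12
        if channel == "fused":
            return _fused_spectrum(self)
        raise ValueError(f"unknown channel {channel!r}")


def _fused_spectrum(entry: LibraryEntry) -> np.ndarray:
    """Response-weighted sum of the two channel spectra, renormalized."""
    from .specmatch import normalize_spectrum

    combined: dict[int, float] = {}
    for spec, resp in ((entry.spectrum_70, entry.response_70),
                       (entry.spectrum_12, entry.response_12)):
        w = resp / spec[:, 1].sum()
        for mz, inten in spec:
            combined[int(mz)] = combined.get(int(mz), 0.0) + inten * w
    arr = np.array(sorted(combined.items()), dtype=float)
    return normalize_spectrum(arr)


class SpectralLibrary:
    """Ordered collection of :class:`LibraryEntry`, addressable by name."""

    def __init__(self, entries: list[LibraryEntry]):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise ValueError("duplicate compound names in library")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key) -> LibraryEntry:
        if isinstance(key, str):
            return self._by_name[key]
        return self.entries[key]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def _normalize_999(mz: np.ndarray, inten: np.ndarray) -> np.ndarray:
    order = np.argsort(mz)
    mz, inten = np.asarray(mz, float)[order], np.asarray(inten, float)[order]
    return np.column_stack([mz, inten * (999.0 / inten.max())])


def _dual_spectra(rng: np.random.Generator, low_frags: np.ndarray,
                  high_frags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Construct a (70 eV, 12 eV) spectrum pair from fragment m/z sets.

    70 eV: low-m/z fragments dominate (base peak among them); high fragments
    present but minor.  12 eV: intensity re-weighted so the largest high-m/z
    fragment is the base peak and low fragments are strongly attenuated.
    """
    lo_i = rng.uniform(150, 999, size=len(low_frags))
    lo_i[rng.integers(len(low_frags))] = 999.0
    hi_i70 = rng.uniform(30, 250, size=len(high_frags))
    mz = np.concatenate([low_frags, high_frags])
    s70 = _normalize_999(mz, np.concatenate([lo_i, hi_i70]))
    hi_i12 = rng.uniform(400, 999, size=len(high_frags))
    hi_i12[rng.integers(len(high_frags))] = 999.0
    lo_i12 = lo_i * rng.uniform(0.08, 0.25, size=len(low_frags))
    s12 = _normalize_999(mz, np.concatenate([lo_i12, hi_i12]))
    return s70, s12


def build_spectral_library(n_compounds: int, seed: int,
                           mz_range: tuple[int, int] = (45, 500),
                           include_named: bool = True) -> SpectralLibrary:
    """Build a reproducible dual-energy library of ``n_compounds`` entries.

    The first entries are the fixed named metabolite subset (with their
    reported retention indices and MUO:MHO effect directions); the remainder
    are randomly generated TMS-like compounds.  ``mz_range`` clips fragments
    to the simulated mass axis.
    """
    if n_compounds < 0:
        raise ValueError("n_compounds must be >= 0")
    rng = np.random.default_rng(seed)
    lo_mz, hi_mz = mz_range
    entries: list[LibraryEntry] = []
    named = NAMED_COMPOUNDS if include_named else ()
    named_low = (73, 75, 117, 129, 147, 204)   # TMS backbone fragments
    for name, ri, high, t2, _ratio in named[: n_compounds]:
        low = np.array([f for f in named_low if lo_mz <= f <= hi_mz])
        high_arr = np.array([f for f in high if lo_mz <= f <= hi_mz])
        if len(high_arr) == 0:
            high_arr = np.array([min(hi_mz, 2 * low.max())])
        s70, s12 = _dual_spectra(rng, low, high_arr)
        resp70 = float(rng.lognormal(np.log(3e7), 0.5))
        resp12 = resp70 / float(rng.uniform(8.0, 15.0))
        entries.append(LibraryEntry(name, float(ri), s70, s12, resp70, resp12, t2))
    n_random = n_compounds - len(entries)
    for k in range(n_random):
        n_low = int(rng.integers(4, 8))
        n_high = int(rng.integers(3, 6))
        low = rng.choice(
            [f for f in _TMS_FRAGMENTS if lo_mz <= f <= min(hi_mz, 160)],
            size=min(n_low, 6), replace=False)
        hi_cap = hi_mz - 5
        high = rng.choice(np.arange(165, max(hi_cap, 180)), size=n_high, replace=False)
        s70, s12 = _dual_spectra(rng, np.sort(low), np.sort(high))
        resp70 = float(rng.lognormal(np.log(3e7), 0.5))
        resp12 = resp70 / float(rng.uniform(8.0, 15.0))
        entries.append(LibraryEntry(
            name=f"compound_{k:03d}",
            ri=float(rng.uniform(950, 2550)),
            spectrum_70=s70,
            spectrum_12=s12,
            response_70=resp70,
            response_12=resp12,
            two_d_time=float(rng.uniform(1.0, 4.4)),
        ))
    return SpectralLibrary(entries)


def reference_class_effects() -> dict[str, float]:
    """MUO:MHO abundance ratios for the curated named metabolite subset."""
    return {name: ratio for name, _ri, _hi, _t2, ratio in NAMED_COMPOUNDS}


@dataclass(frozen=True)
class RunKey:
    """Stable identifier for one analytical run of the study design."""

    run_id: str
    subject_id: str
    group: str
    process_rep: int
    analytical_rep: int


@dataclass
class StudyDesign:
    runs: list[RunKey]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def groups(self) -> list[str]:
        return [r.group for r in self.runs]

    def subjects(self) -> list[tuple[str, str]]:
        seen: dict[str, str] = {}
        for r in self.runs:
            seen.setdefault(r.subject_id, r.group)
        return list(seen.items())


def make_study_design(n_qc: int, n_mho: int, n_muo: int,
                      process_reps: int, analytical_reps: int) -> StudyDesign:
    """Enumerate every (subject, process rep, analytical rep) run.

    The default study layout (4, 3, 5, 2, 2) yields 48 runs; the QC subset
    (4, 0, 0, 2, 2) yields 16.
    """
    for name, v in (("n_qc", n_qc), ("n_mho", n_mho), ("n_muo", n_muo)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if process_reps < 1 or analytical_reps < 1:
        raise ValueError("replicate counts must be >= 1")
    subjects = (
        [(f"QC{i+1}", "QC") for i in range(n_qc)]
        + [(f"MHO{i+1}", "MHO") for i in range(n_mho)]
        + [(f"MUO{i+1}", "MUO") for i in range(n_muo)]
    )
    runs = [
        RunKey(f"{sid}_p{p+1}_a{a+1}", sid, grp, p + 1, a + 1)
        for sid, grp in subjects
        for p in range(process_reps)
        for a in range(analytical_reps)
    ]
    return StudyDesign(runs)


@dataclass
class SynthConfig:
    """Acquisition and noise parameters of the simulated instrument.

    Defaults mirror the emulated platform: 5 s modulation, 50 Hz per channel
    (250 samples per modulation), retention jitter 0.20% RSD in ¹D and 1.90%
    in ²D, 70 eV TIC background ≈ 23,000 counts with robust noise σ 5,000
    (so S/N 100 ⇒ 500,000 counts) and a 12 eV background roughly one order of
    magnitude lower (σ 50 ⇒ 5,000 counts at S/N 100).
    """

    modulation_period: float = 5.0            # s
    acquisition_rate: float = 50.0            # Hz per channel
    n_modulations: int = 400
    mz_range: tuple[int, int] = (45, 500)     # Da, inclusive integer bins
    # oven program (minutes → °C) used only to place alkanes/RI on the ¹D axis
    oven_ramp: tuple[tuple[float, float], ...] = (
        (0.0, 70.0), (2.0, 70.0), (7.0, 120.0), (57.0, 320.0), (58.0, 320.0))
    rt_jitter_1d: float = 0.20                # % RSD of ¹D retention time
    rt_jitter_2d: float = 1.90                # % RSD of ²D retention time
    baseline_level_70: float = 23000.0        # TIC counts (bleed ramp mean)
    baseline_level_12: float = 1840.0
    noise_sigma_70: float = 5000.0            # Gaussian TIC noise σ, counts
    noise_sigma_12: float = 50.0
    shot_noise: bool = True                   # Poisson on blob counts
    sigma1_modulations: float = 1.0           # ¹D peak σ, modulation units
    sigma2_s: float = 0.05                    # ²D peak σ, seconds
    class_effects: dict = field(default_factory=dict)  # name → MUO:MHO ratio
    subject_cv: float = 0.10                  # biological log-sd between subjects
    process_cv: float = 0.10                  # process-replicate log-sd
    analytical_cv: float = 0.05               # analytical-replicate log-sd
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.modulation_period * self.acquisition_rate
        if abs(p - round(p)) > 1e-9 or p <= 0:
            raise ValueError(
                "modulation_period × acquisition_rate must be a positive integer")
        if self.rt_jitter_1d < 0 or self.rt_jitter_2d < 0:
            raise ValueError("jitter RSDs must be >= 0")

    @property
    def samples_per_modulation(self) -> int:
        return int(round(self.modulation_period * self.acquisition_rate))

    @property
    def run_minutes(self) -> float:
        return self.n_modulations * self.modulation_period / SECONDS_PER_MINUTE

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_range[0], self.mz_range[1] + 1)

    def alkane_rt1_minutes(self) -> np.ndarray:
        """¹D elution times (min) of n-C7…n-C30 under the configured ramp.

        Alkane elution temperatures are spread linearly from 90 °C (C7) to
        315 °C (C30); each is inverted through the piecewise-linear oven
        program and the resulting times rescaled into the simulated run
        length.  This reproduces the near-linear carbon-number/time relation
        of temperature-programmed separations without thermodynamics.
        """
        times = np.array([t for t, _ in self.oven_ramp])
        temps = np.array([T for _, T in self.oven_ramp])
        elution_T = np.linspace(90.0, 315.0, len(ALKANE_CARBONS))
        # invert the (monotone past the hold) ramp: temperature → time
        t_prog = np.interp(elution_T, temps, times)
        scale = 0.95 * self.run_minutes / times[-1]
        return t_prog * scale + 0.02 * self.run_minutes

    def ri_to_rt1(self, ri) -> np.ndarray:
        """Map retention index → ¹D time (min) on the alkane grid."""
        grid_ri = 100.0 * np.array(ALKANE_CARBONS, dtype=float)
        return np.interp(np.asarray(ri, float), grid_ri, self.alkane_rt1_minutes())


# Column-bleed mass spectrum used to distribute background TIC over m/z
# (polysiloxane fragments), normalized to unit sum over the configured range.
_BLEED_FRAGMENTS = ((73, 100.0), (147, 40.0), (207, 60.0), (221, 20.0),
                    (281, 35.0), (327, 10.0), (355, 15.0), (429, 8.0))


def _bleed_profile(mz_axis: np.ndarray) -> np.ndarray:
    prof = np.zeros(len(mz_axis))
    lo = mz_axis[0]
    for mz, w in _BLEED_FRAGMENTS:
        if mz_axis[0] <= mz <= mz_axis[-1]:
            prof[mz - lo] = w
    if prof.sum() == 0:
        prof[:] = 1.0
    return prof / prof.sum()


@dataclass
class SimulatedRun:
    """Raw dual-channel output of one simulated analytical run."""

    run: RunKey | None
    stream_70: np.ndarray          # (time, m/z) detector stream
    stream_12: np.ndarray
    mz_axis: np.ndarray
    modulation_period: float
    acquisition_rate: float
    truth: pd.DataFrame            # per-compound ground-truth table

    def chromatogram(self, channel: str) -> Chromatogram2D:
        from .gc2d import fold

        stream = {"70eV": self.stream_70, "12eV": self.stream_12}[channel]
        return fold(stream, self.modulation_period, self.acquisition_rate,
                    self.mz_axis, channel=channel,
                    run_id=self.run.run_id if self.run else "")


def _spectrum_fractions(spectrum: np.ndarray, mz_axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip a spectrum to the mass axis; return (bin indices, unit fractions)."""
    lo, hi = mz_axis[0], mz_axis[-1]
    keep = (spectrum[:, 0] >= lo) & (spectrum[:, 0] <= hi)
    mz = spectrum[keep, 0].astype(int)
    inten = spectrum[keep, 1].astype(float)
    if inten.sum() <= 0:
        raise ValueError("spectrum has no fragments inside the mass axis")
    return mz - int(lo), inten / inten.sum()


def _baseline_tic(config: SynthConfig, level: float, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    n_mod, p = config.n_modulations, config.samples_per_modulation
    ramp = level * (0.6 + 0.8 * np.linspace(0.0, 1.0, n_mod))  # monotone bleed
    img = np.repeat(ramp[:, None], p, axis=1).astype(np.float32)
    if sigma > 0:
        img += rng.normal(0.0, sigma, size=(n_mod, p)).astype(np.float32)
    np.clip(img, 0.0, None, out=img)
    return img


def _add_blob(cube: np.ndarray, c1: float, c2: float, volume: float,
              frac_idx: np.ndarray, fracs: np.ndarray, config: SynthConfig,
              rng: np.random.Generator) -> float:
    """Deposit one 2D-Gaussian compound blob into the cube; return its TIC volume."""
    n_mod, p, _ = cube.shape
    s1 = config.sigma1_modulations
    s2 = config.sigma2_s * config.acquisition_rate
    i0, i1 = max(0, int(c1 - 4 * s1)), min(n_mod, int(c1 + 4 * s1) + 2)
    j0, j1 = max(0, int(c2 - 4 * s2)), min(p, int(c2 + 4 * s2) + 2)
    if i0 >= i1 or j0 >= j1:
        return 0.0
    ii = np.arange(i0, i1)[:, None]
    jj = np.arange(j0, j1)[None, :]
    w = np.exp(-0.5 * (((ii - c1) / s1) ** 2 + ((jj - c2) / s2) ** 2))
    w_sum = w.sum()
    if w_sum <= 0:
        return 0.0
    w *= volume / w_sum
    lam = w[:, :, None] * fracs[None, None, :]
    if config.shot_noise:
        counts = rng.poisson(lam).astype(np.float32)
    else:
        counts = lam.astype(np.float32)
    block = cube[i0:i1, j0:j1]          # basic-slice view: writes through
    block[:, :, frac_idx] += counts
    return float(counts.sum(dtype=np.float64))


def simulate_run(design_entry: RunKey | None, library: SpectralLibrary,
                 abundances, config: SynthConfig, seed: int) -> SimulatedRun:
    """Simulate the two raw channel streams of one analytical run.

    ``abundances`` is one scalar per library entry (in library order).  MUO
    runs additionally scale each compound by ``config.class_effects`` so that
    the true-volume MUO:MHO ratio of a compound equals its configured ratio
    exactly.  Ground truth (jittered apex positions, true channel volumes) is
    returned in ``truth``.
    """
    abundances = np.asarray(abundances, dtype=float)
    if len(abundances) != len(library):
        raise ValueError(
            f"abundance vector length {len(abundances)} != library size {len(library)}")
    rng = np.random.default_rng(seed)
    mz_axis = config.mz_axis
    n_mod, p = config.n_modulations, config.samples_per_modulation
    group = design_entry.group if design_entry is not None else "QC"

    cubes = {
        "70eV": _baseline_tic(config, config.baseline_level_70,
                              config.noise_sigma_70, rng)[:, :, None]
        * _bleed_profile(mz_axis)[None, None, :].astype(np.float32),
        "12eV": _baseline_tic(config, config.baseline_level_12,
                              config.noise_sigma_12, rng)[:, :, None]
        * _bleed_profile(mz_axis)[None, None, :].astype(np.float32),
    }

    records = []
    for entry, abund in zip(library, abundances):
        if group == "MUO":
            abund = abund * config.class_effects.get(entry.name, 1.0)
        rt1_true = float(config.ri_to_rt1(entry.ri))
        rt2_true = entry.two_d_time
        rt1 = rt1_true * (1.0 + rng.normal() * config.rt_jitter_1d / 100.0)
        rt2 = rt2_true * (1.0 + rng.normal() * config.rt_jitter_2d / 100.0)
        c1 = rt1 * SECONDS_PER_MINUTE / config.modulation_period
        c2 = (rt2 % config.modulation_period) * config.acquisition_rate
        rec = {"name": entry.name, "ri": entry.ri, "group": group,
               "rt1_true_min": rt1_true, "rt2_true_s": rt2_true,
               "rt1_min": rt1, "rt2_s": rt2, "abundance": abund}
        for channel, resp in (("70eV", entry.response_70), ("12eV", entry.response_12)):
            idx, fracs = _spectrum_fractions(entry.spectrum(channel), mz_axis)
            vol = abund * resp
            realized = _add_blob(cubes[channel], c1, c2, vol, idx, fracs, config, rng)
            rec[f"volume_{channel}"] = vol
            rec[f"realized_{channel}"] = realized
        records.append(rec)

    truth = pd.DataFrame(
        records,
        columns=["name", "ri", "group", "rt1_true_min", "rt2_true_s", "rt1_min",
                 "rt2_s", "abundance", "volume_70eV", "realized_70eV",
                 "volume_12eV", "realized_12eV"])
    return SimulatedRun(
        run=design_entry,
        stream_70=cubes["70eV"].reshape(n_mod * p, len(mz_axis)),
        stream_12=cubes["12eV"].reshape(n_mod * p, len(mz_axis)),
        mz_axis=mz_axis,
        modulation_period=config.modulation_period,
        acquisition_rate=config.acquisition_rate,
        truth=truth,
    )


_ALKANE_SPECTRUM = np.array(
    [[57, 999.0], [71, 700.0], [85, 450.0], [99, 180.0], [113, 90.0]])


def simulate_alkane_run(config: SynthConfig, seed: int = 0) -> SimulatedRun:
    """Simulate the n-alkane (C7–C30) calibration run.

    One blob per alkane at monotonically increasing ¹D time, no retention
    jitter (calibration standards are injected once); ground truth maps
    carbon number → ¹D time.
    """
    rng = np.random.default_rng(seed)
    mz_axis = config.mz_axis
    n_mod, p = config.n_modulations, config.samples_per_modulation
    cube = (_baseline_tic(config, config.baseline_level_70,
                          config.noise_sigma_70, rng)[:, :, None]
            * _bleed_profile(mz_axis)[None, None, :].astype(np.float32))
    idx, fracs = _spectrum_fractions(_ALKANE_SPECTRUM, mz_axis)
    times = config.alkane_rt1_minutes()
    records = []
    for carbon, rt1 in zip(ALKANE_CARBONS, times):
        c1 = rt1 * SECONDS_PER_MINUTE / config.modulation_period
        rt2 = 1.1 + 0.002 * (carbon - 7)
        c2 = rt2 * config.acquisition_rate
        realized = _add_blob(cube, c1, c2, 8e6, idx, fracs, config, rng)
        records.append({"carbon_number": carbon, "rt1_min": rt1,
                        "rt2_s": rt2, "realized": realized})
    truth = pd.DataFrame(records)
    stream = cube.reshape(n_mod * p, len(mz_axis))
    return SimulatedRun(
        run=RunKey("alkanes", "alkanes", "QC", 1, 1),
        stream_70=stream, stream_12=stream, mz_axis=mz_axis,
        modulation_period=config.modulation_period,
        acquisition_rate=config.acquisition_rate, truth=truth)


def simulate_study(design: StudyDesign, library: SpectralLibrary,
                   config: SynthConfig, seed: int):
    """Yield one :class:`SimulatedRun` per design run.

    Per-compound abundances combine a subject-level biological lognormal
    (``subject_cv``) with process- and analytical-replicate lognormals,
    emulating the response repeatability structure of replicated injections.
    Seeds are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(ss.spawn(1)[0])
    base: dict[str, np.ndarray] = {}
    for sid, _grp in design.subjects():
        base[sid] = np.exp(subj_rng.normal(0.0, config.subject_cv, size=len(library)))
    run_seeds = ss.spawn(len(design.runs) + 1)[1:]
    rep_rng = np.random.default_rng(ss.spawn(1)[0])
    process_factors: dict[tuple[str, int], np.ndarray] = {}
    for run in design.runs:
        key = (run.subject_id, run.process_rep)
        if key not in process_factors:
            process_factors[key] = np.exp(
                rep_rng.normal(0.0, config.process_cv, size=len(library)))
    for run, rs in zip(design.runs, run_seeds):
        rep = (base[run.subject_id]
               * process_factors[(run.subject_id, run.process_rep)]
               * np.exp(rep_rng.normal(0.0, config.analytical_cv, size=len(library))))
        child = int(rs.generate_state(1)[0] % (2**31 - 1))
        yield simulate_run(run, library, rep, config, seed=child)
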