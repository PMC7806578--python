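"""Core GC×GC data model and I/O.

A comprehensive two-dimensional gas chromatography (GC×GC) run is acquired as a
single detector stream: at every acquisition tick the TOF records one mass
spectrum.  A thermal modulator re-injects the first-column (¹D) effluent onto
the short second column (²D) every ``modulation_period`` seconds, so the stream
folds into a data cube indexed by

    (modulation index, intra-modulation sample, m/z bin).

The ¹D retention time of modulation column ``k`` is ``k * modulation_period``
(reported in minutes); the ²D time of row ``j`` is ``j / acquisition_rate``
(seconds).  Both axes start at 0 for the first sample and no injection-delay
offset is applied.

Containers are read and written in a simple HDF5 layout (``/cube``,
``/mz_axis``, ``/meta``) and in scan-based ANDI-MS style netCDF (classic
NetCDF-3, via :mod:`scipy.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.io import netcdf_file

CHANNELS = ("70eV", "12eV", "fused")

SECONDS_PER_MINUTE = 60.0


@dataclass
class Chromatogram2D:
    """A per-run, per-channel GC×GC data cube.

    Attributes
    ----------
    cube : ndarray, shape (n_modulations, samples_per_modulation, n_mz)
        Ion counts.
    mz_axis : ndarray of int
        Nominal (integer-binned) m/z values, strictly increasing.
    modulation_period : float
        Seconds between modulator injections.
    acquisition_rate : float
        Spectra per second per channel (Hz).
    channel : str
        One of ``"70eV"``, ``"12eV"``, ``"fused"``.
    run_id : str
    """

    cube: np.ndarray
    mz_axis: np.ndarray
    modulation_period: float
    acquisition_rate: float
    channel: str
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        p = self.modulation_period * self.acquisition_rate
        n = self.cube.shape[1]
        if abs(p - round(p)) > 1e-9 or int(round(p)) != n:
            raise ValueError(
                f"cube has {n} intra-modulation samples but modulation_period × "
                f"acquisition_rate = {p}"
            )
        if self.cube.shape[2] != len(self.mz_axis):
            raise ValueError("cube m/z dimension does not match mz_axis length")

    @property
    def n_modulations(self) -> int:
        return self.cube.shape[0]

    @property
    def samples_per_modulation(self) -> int:
        return self.cube.shape[1]

    def rt1_minutes(self) -> np.ndarray:
        """¹D retention time of each modulation column, minutes."""
        return np.arange(self.n_modulations) * self.modulation_period / SECONDS_PER_MINUTE

    def rt2_seconds(self) -> np.ndarray:
        """²D elution time of each intra-modulation sample, seconds."""
        return np.arange(self.samples_per_modulation) / self.acquisition_rate

    def flatten(self) -> np.ndarray:
        """Unfold the cube back into the raw (time, m/z) detector stream."""
        return self.cube.reshape(-1, self.cube.shape[2])


@dataclass
class TICImage:
    """Total-ion-current image of a run: cube summed over m/z.

    ``image[i, j]`` is the TIC at modulation ``i``, intra-modulation sample
    ``j``; axes are carried so peak coordinates can be reported in minutes
    (¹D) and seconds (²D).
    """

    image: np.ndarray
    modulation_period: float
    acquisition_rate: float
    channel: str = "70eV"
    run_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def rt1_minutes(self) -> np.ndarray:
        return np.arange(self.image.shape[0]) * self.modulation_period / SECONDS_PER_MINUTE

    def rt2_seconds(self) -> np.ndarray:
        return np.arange(self.image.shape[1]) / self.acquisition_rate

    def pixel_to_rt(self, i: int | np.ndarray, j: int | np.ndarray) -> tuple:
        """Map (modulation, sample) pixel indices to (¹D min, ²D s)."""
        rt1 = np.asarray(i) * self.modulation_period / SECONDS_PER_MINUTE
        rt2 = np.asarray(j) / self.acquisition_rate
        return rt1, rt2

    def rt_to_pixel(self, rt1_min, rt2_s) -> tuple:
        """Inverse of :meth:`pixel_to_rt` (fractional pixel coordinates)."""
        i = np.asarray(rt1_min) * SECONDS_PER_MINUTE / self.modulation_period
        j = np.asarray(rt2_s) * self.acquisition_rate
        return i, j

    def copy_with(self, image: np.ndarray) -> "TICImage":
        return TICImage(
            image=image,
            modulation_period=self.modulation_period,
            acquisition_rate=self.acquisition_rate,
            channel=self.channel,
            run_id=self.run_id,
        )


def fold(stream: np.ndarray, modulation_period: float, acquisition_rate: float,
         mz_axis: np.ndarray, channel: str = "70eV", run_id: str = "") -> Chromatogram2D:
    """Fold a raw (time × m/z) detector stream into a 2D chromatogram.

    ``P = modulation_period * acquisition_rate`` consecutive spectra make up
    one modulation column; the stream length must be an exact multiple of P so
    that no data are dropped.
    """
    stream = np.asarray(stream)
    p_float = modulation_period * acquisition_rate
    p = int(round(p_float))
    if abs(p_float - p) > 1e-9 or p <= 0:
        raise ValueError(
            f"modulation_period × acquisition_rate must be a positive integer, got {p_float}"
        )
    n = stream.shape[0]
    if n % p != 0:
        raise ValueError(
            f"stream length {n} not divisible by {p} samples per modulation "
            f"(remainder {n % p})"
        )
    cube = stream.reshape(n // p, p, stream.shape[1])
    return Chromatogram2D(
        cube=cube,
        mz_axis=np.asarray(mz_axis),
        modulation_period=modulation_period,
        acquisition_rate=acquisition_rate,
        channel=channel,
        run_id=run_id,
    )


def tic(chrom: Chromatogram2D) -> TICImage:
    """Pixel-wise sum of the cube over m/z."""
    return TICImage(
        image=chrom.cube.sum(axis=2, dtype=np.float64),
        modulation_period=chrom.modulation_period,
        acquisition_rate=chrom.acquisition_rate,
        channel=chrom.channel,
        run_id=chrom.run_id,
    )


_META_FIELDS = ("modulation_period", "acquisition_rate", "channel", "run_id")


def write_run(chrom: Chromatogram2D, path: str | Path) -> None:
    """Write a run in the HDF5 layout (/cube, /mz_axis, /meta attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=chrom.cube)
        f.create_dataset("mz_axis", data=np.asarray(chrom.mz_axis))
        meta = f.create_group("meta")
        meta.attrs["modulation_period"] = chrom.modulation_period
        meta.attrs["acquisition_rate"] = chrom.acquisition_rate
        meta.attrs["channel"] = chrom.channel
        meta.attrs["run_id"] = chrom.run_id


def read_run(path: str | Path) -> Chromatogram2D:
    """Read a run written by :func:`write_run`."""
    with h5py.File(path, "r") as f:
        if "cube" not in f or "mz_axis" not in f or "meta" not in f:
            missing = [k for k in ("cube", "mz_axis", "meta") if k not in f]
            raise ValueError(f"not a run container; missing datasets: {missing}")
        meta = f["meta"].attrs
        absent = [k for k in _META_FIELDS if k not in meta]
        if absent:
            raise ValueError(f"run container missing metadata fields: {absent}")
        return Chromatogram2D(
            cube=f["cube"][()],
            mz_axis=f["mz_axis"][()],
            modulation_period=float(meta["modulation_period"]),
            acquisition_rate=float(meta["acquisition_rate"]),
            channel=str(meta["channel"]),
            run_id=str(meta["run_id"]),
        )


def write_run_cdf(chrom: Chromatogram2D, path: str | Path) -> None:
    """Write a run as scan-based ANDI-MS style classic netCDF.

    Every acquisition tick becomes one scan; each scan stores the full integer
    m/z axis with its intensity vector, mirroring the
    ``mass_values``/``intensity_values``/``scan_index`` layout of ANDI-MS
    (netCDF-3 classic, so readable without HDF5-backed netCDF-4 libraries).
    """
    stream = chrom.flatten()
    n_scans, n_mz = stream.shape
    with netcdf_file(str(path), "w") as f:
        f.createDimension("scan_number", n_scans)
        f.createDimension("point_number", n_scans * n_mz)
        scan_index = f.createVariable("scan_index", "i", ("scan_number",))
        scan_index[:] = np.arange(n_scans, dtype=np.int32) * n_mz
        scan_time = f.createVariable("scan_acquisition_time", "d", ("scan_number",))
        scan_time[:] = np.arange(n_scans) / chrom.acquisition_rate
        mass = f.createVariable("mass_values", "d", ("point_number",))
        mass[:] = np.tile(np.asarray(chrom.mz_axis, dtype=np.float64), n_scans)
        inten = f.createVariable("intensity_values", "d", ("point_number",))
        inten[:] = stream.astype(np.float64).ravel()
        f.modulation_period = chrom.modulation_period
        f.acquisition_rate = chrom.acquisition_rate
        f.channel = chrom.channel.encode()
        f.run_id = chrom.run_id.encode()
        f.sync()


def read_run_cdf(path: str | Path) -> Chromatogram2D:
    """Read a scan-based netCDF run written by :func:`write_run_cdf`."""
    with netcdf_file(str(path), "r", mmap=False) as f:
        for name in ("scan_index", "mass_values", "intensity_values"):
            if name not in f.variables:
                raise ValueError(f"netCDF run missing variable {name!r}")
        absent = [k for k in _META_FIELDS if not hasattr(f, k)]
        if absent:
            raise ValueError(f"netCDF run missing metadata attributes: {absent}")
        scan_index = f.variables["scan_index"][:]
        n_scans = len(scan_index)
        mass = f.variables["mass_values"][:]
        inten = f.variables["intensity_values"][:]
        n_mz = len(mass) // n_scans
        mz_axis = mass[:n_mz].astype(int)
        stream = inten.reshape(n_scans, n_mz)
        channel = f.channel
        run_id = f.run_id
        if isinstance(channel, bytes):
            channel = channel.decode()
        if isinstance(run_id, bytes):
            run_id = run_id.decode()
        return fold(
            stream,
            float(f.modulation_period),
            float(f.acquisition_rate),
            mz_axis,
            channel=channel,
            run_id=run_id,
        )
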