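"""NIST-style spectral similarity on the 0–999 scale.

Spectra are (n, 2) float arrays of (integer m/z, intensity), base peak
normalized to 999.  The direct match factor (DMF) is the Stein–Scott
identity-weighted cosine between two spectra over the union of their m/z
values, with weights ``w = intensity**0.6 * mz**3``:

    DMF = round(999 * (Σ √(w_a w_b))² / (Σ w_a · Σ w_b))

The reverse match factor (RMF) is the same score computed only over the m/z
present in the reference spectrum, so impurity peaks in the query are
ignored — the standard "reverse search" used when matching a measured peak
spectrum against a clean library record.

Only the weighted cosine term is implemented; the NIST composite score's
ratio-of-adjacent-peaks term is deliberately omitted (see the methods note).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

#: Stein–Scott identity-search weighting exponents (intensity, m/z).
DEFAULT_WEIGHTS = (0.6, 3.0)

BASE_PEAK = 999.0


def _as_spectrum(s) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("spectrum must be a non-empty (n, 2) array of (mz, intensity)")
    return arr


def normalize_spectrum(s) -> np.ndarray:
    """Scale a spectrum so its base peak is 999; sort by m/z.

    Relative intensities are preserved, making the operation idempotent.
    """
    arr = _as_spectrum(s)
    top = arr[:, 1].max()
    if top <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    order = np.argsort(arr[:, 0])
    out = arr[order].copy()
    out[:, 1] *= BASE_PEAK / top
    return out


def _weighted(spec: np.ndarray, exponents: tuple[float, float]) -> dict[int, float]:
    ei, em = exponents
    return {int(mz): float(inten ** ei * mz ** em)
            for mz, inten in spec if inten > 0}


def _cosine_score(wa: dict[int, float], wb: dict[int, float]) -> int:
    sa, sb = sum(wa.values()), sum(wb.values())
    if sa <= 0 or sb <= 0:
        return 0
    cross = sum(np.sqrt(wa[mz] * wb[mz]) for mz in wa.keys() & wb.keys())
    return int(round(BASE_PEAK * cross * cross / (sa * sb)))


def direct_match_factor(a, b, exponents: tuple[float, float] = DEFAULT_WEIGHTS) -> int:
    """Weighted-cosine similarity of two spectra over the union of m/z."""
    wa = _weighted(_as_spectrum(a), exponents)
    wb = _weighted(_as_spectrum(b), exponents)
    if not wa or not wb:
        raise ValueError("spectra must contain at least one positive intensity")
    return _cosine_score(wa, wb)


def reverse_match_factor(query, reference,
                         exponents: tuple[float, float] = DEFAULT_WEIGHTS) -> int:
    """DMF restricted to the reference's m/z values (query extras ignored)."""
    wq = _weighted(_as_spectrum(query), exponents)
    wr = _weighted(_as_spectrum(reference), exponents)
    if not wr:
        raise ValueError("reference spectrum must contain positive intensities")
    wq_restricted = {mz: w for mz, w in wq.items() if mz in wr}
    return _cosine_score(wq_restricted, wr)


def match_factors(query, reference,
                  exponents: tuple[float, float] = DEFAULT_WEIGHTS) -> tuple[int, int]:
    """(DMF, RMF) of a query spectrum against a reference."""
    return (direct_match_factor(query, reference, exponents),
            reverse_match_factor(query, reference, exponents))


def write_msp(entries: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named spectra in NIST MSP text format."""
    with open(path, "w") as f:
        for name, spec in entries.items():
            arr = _as_spectrum(spec)
            f.write(f"Name: {name}\n")
            f.write(f"Num Peaks: {len(arr)}\n")
            for mz, inten in arr:
                f.write(f"{int(mz)} {inten:.1f};\n")
            f.write("\n")


def read_msp(path: str | Path) -> dict[str, np.ndarray]:
    """Read an MSP file written by :func:`write_msp` (or NIST-style text)."""
    entries: dict[str, np.ndarray] = {}
    name = None
    peaks: list[tuple[float, float]] = []
    with open(path) as f:
        for raw in f:
            line = raw.strip()
            if not line:
                if name is not None and peaks:
                    entries[name] = np.array(peaks)
                name, peaks = None, []
                continue
            low = line.lower()
            if low.startswith("name:"):
                name = line.split(":", 1)[1].strip()
            elif ":" in line and not line[0].isdigit():
                continue  # other header fields (Num Peaks, CAS, ...)
            else:
                tokens = line.replace(";", " ").replace(",", " ").split()
                for mz_tok, int_tok in zip(tokens[::2], tokens[1::2]):
                    peaks.append((float(mz_tok), float(int_tok)))
    if name is not None and peaks:
        entries[name] = np.array(peaks)
    return entries
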