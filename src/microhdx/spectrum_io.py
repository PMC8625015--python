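"""Peak-list I/O, replicate averaging and total-ion-current normalization.

The canonical on-disk format is a two-column tab-separated peak list
(mz<TAB>intensity, '#'-prefixed comment lines allowed) — the plain-text
export a practitioner gets from Xcalibur.  Centroided mzML is read through
pyteomics behind the same Spectrum type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
    "tic_normalize",
    "average_spectra",
]


class PeaklistParseError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Centroided spectrum: sorted m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if (inten < 0).any():
            raise ValueError("negative intensity")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


def read_peaklist(path: str | Path) -> Spectrum:
    """Read a two-column TSV peak list; peaks come back sorted by m/z."""
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise PeaklistParseError(
                    f"{path}: non-numeric peak row at line {lineno}: {line!r}"
                ) from exc
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise PeaklistParseError(f"{path}: empty spectrum")
    return Spectrum(np.array(mzs), np.array(intens), {"source": str(path)})


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mz\tintensity\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6g}\n")


def read_mzml(path: str | Path, scan_index: int = 0) -> Spectrum:
    """Read one centroided scan from an mzML file (optional input path)."""
    from pyteomics import mzml as _mzml

    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if i == scan_index:
                return Spectrum(
                    np.asarray(scan["m/z array"], dtype=float),
                    np.asarray(scan["intensity array"], dtype=float),
                    {"source": str(path), "scan": scan.get("id", scan_index)},
                )
    raise IndexError(f"scan {scan_index} not found in {path}")


def tic_normalize(spectrum: Spectrum, total: float = 100.0) -> Spectrum:
    """Scale intensities so their sum equals ``total`` (default 100)."""
    tic = spectrum.tic
    if tic <= 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return Spectrum(
        spectrum.mz, spectrum.intensity * (total / tic), dict(spectrum.metadata)
    )


def average_spectra(spectra: list[Spectrum], mz_tol: float = 0.002) -> Spectrum:
    """Average replicate spectra, merging peaks within ``mz_tol``.

    Peaks from all spectra are pooled, clustered by single linkage on the m/z
    axis (gap < mz_tol joins), and each cluster becomes one averaged peak:
    intensity = cluster total / number of spectra (a peak absent from a
    spectrum contributes zero), m/z = intensity-weighted mean.  The default
    tolerance is the instrument peak width (FWHM ~0.002 at R = 120,000).
    """
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    n = len(spectra)
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    breaks = np.nonzero(np.diff(mz) >= mz_tol)[0] + 1
    out_mz, out_inten = [], []
    for grp_mz, grp_in in zip(np.split(mz, breaks), np.split(inten, breaks)):
        total = grp_in.sum()
        if total > 0:
            out_mz.append(float(grp_mz @ grp_in) / total)
        else:
            out_mz.append(float(grp_mz.mean()))
        out_inten.append(total / n)
    return Spectrum(np.array(out_mz), np.array(out_inten), {"n_averaged": n})
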