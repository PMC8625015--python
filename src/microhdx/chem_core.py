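"""Chemical formulas, adduct ion m/z, ppm matching and natural isotope patterns.

Monoisotopic masses and isotopic abundances are taken from the NIST table
shipped with :mod:`pyteomics` (CODATA/IUPAC values), which is treated as the
pinned mass table of this package.  All ion m/z values carry the electron-mass
correction, which is required to reproduce printed high-resolution values such
as [M+H]+ 300.1594 for C18H21NO3 at four decimal places.

Isotope patterns are aggregated per *nominal* mass offset (0, 1, 2, ... Da
above the monoisotopic peak): at a resolving power of 120,000 the instrument
does not separate the fine structure of 13C, 2H and 15N substitutions, so the
merged channels are what the spectrum actually shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

ELECTRON_MASS = _pmass.nist_mass["e*"][0][0]
PROTON_MASS = _pmass.nist_mass["H"][0][0] - ELECTRON_MASS
#: Mass gained by one H -> D replacement, m(2H) - m(1H).  Rounds to 1.0063.
DEUTERIUM_STEP = _pmass.nist_mass["H"][2][0] - _pmass.nist_mass["H"][1][0]

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "DEUTERIUM_STEP",
    "Formula",
    "Adduct",
    "ADDUCTS",
    "IsotopePattern",
    "parse_formula",
    "ion_mz",
    "ppm_match",
    "natural_pattern",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically unknown formula strings."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition of a neutral molecule."""

    element_counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if n < 1:
                raise FormulaError(f"non-positive count for element {el!r}: {n}")

    def monoisotopic_mass(self) -> float:
        return float(
            _pmass.calculate_mass(composition=_pmass.Composition(self.element_counts))
        )

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.element_counts.items()})

    def format(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        counts = dict(self.element_counts)
        order = [el for el in ("C", "H") if el in counts]
        order += sorted(el for el in counts if el not in ("C", "H"))
        return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``"C18H21NO3"``.

    Implicit count 1 is allowed (``"NO3"`` means one N, three O).  Unknown
    element symbols or leftover junk raise :class:`FormulaError` naming the
    offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    try:
        comp = _pmass.Composition(formula=text.strip())
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise FormulaError(f"malformed formula {text!r}: {exc}") from exc
    counts = {el: int(n) for el, n in comp.items() if n}
    for el in counts:
        if el not in _pmass.nist_mass:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
    if not counts:
        raise FormulaError(f"formula {text!r} contains no atoms")
    return Formula(counts)


@dataclass(frozen=True)
class Adduct:
    """Ionization adduct; ``proton_bearing`` marks a charging species that is
    itself an exchangeable proton/deuteron (true for [M+H]+, false for [M+Na]+).
    """

    name: str
    mass_delta: float
    charge: int
    multimer: int = 1
    proton_bearing: bool = True

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.multimer < 1:
            raise ValueError("multimer count must be >= 1")


ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", PROTON_MASS + ELECTRON_MASS, +1, 1, True),
    "[M+Na]+": Adduct(
        "[M+Na]+", _pmass.nist_mass["Na"][0][0], +1, 1, False
    ),
    "[2M+H]+": Adduct("[2M+H]+", PROTON_MASS + ELECTRON_MASS, +1, 2, True),
    "[M-H]-": Adduct("[M-H]-", -(PROTON_MASS + ELECTRON_MASS), -1, 1, True),
}
# mass_delta above is the *atomic* delta (H atom / Na atom); the electron is
# removed explicitly in ion_mz so that the correction is applied exactly once
# whatever the charge sign.


def ion_mz(formula: Formula, adduct: Adduct) -> float:
    """m/z of the adduct ion, electron-corrected, full double precision."""
    m = adduct.multimer * formula.monoisotopic_mass() + adduct.mass_delta
    return (m - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff ``observed`` lies within ``tol_ppm`` of ``theoretical``."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    return 1e6 * abs(observed - theoretical) / theoretical <= tol_ppm


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances at nominal mass offsets 0, 1, 2, ... above the
    monoisotopic (all-lightest) isotopologue; entries are probabilities and
    sum to <= 1 after truncation."""

    abundances: np.ndarray
    truncation_length: int = field(default=0)

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", a)
        if self.truncation_length == 0:
            object.__setattr__(self, "truncation_length", len(a))
        if a[0] <= 0:
            raise ValueError("monoisotopic abundance must be positive")
        if (a < -1e-15).any():
            raise ValueError("negative isotope abundance")
        if a.sum() > 1 + 1e-9:
            raise ValueError("isotope abundances sum above 1")


def _element_offset_pmf(el: str) -> np.ndarray:
    """Per-atom probability vector over nominal mass offsets for one element."""
    iso = _pmass.nist_mass[el]
    entries = [(num, m, ab) for num, (m, ab) in iso.items() if num != 0 and ab > 0]
    if not entries:
        raise KeyError(f"no isotope abundance data for element {el!r}")
    lightest = min(m for _, m, _ in entries)
    pmf: dict[int, float] = {}
    for _, m, ab in entries:
        off = int(round(m - lightest))
        pmf[off] = pmf.get(off, 0.0) + ab
    out = np.zeros(max(pmf) + 1)
    for off, ab in pmf.items():
        out[off] = ab
    return out / out.sum()


def natural_pattern(formula: Formula, length: int) -> IsotopePattern:
    """Natural-abundance isotope pattern of ``formula`` by per-element
    polynomial convolution, truncated to ``length`` nominal-offset channels."""
    if length < 1:
        raise ValueError("pattern length must be >= 1")
    pattern = np.array([1.0])
    for el, n in formula.element_counts.items():
        atom = _element_offset_pmf(el)
        if len(atom) == 1:
            continue  # monoisotopic element contributes nothing
        for _ in range(n):
            pattern = np.convolve(pattern, atom)[:length]
    out = np.zeros(length)
    out[: len(pattern)] = pattern
    return IsotopePattern(out, truncation_length=length)
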