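"""Deuterium-ladder extraction and interpretation.

A deuterium ladder is the series of peaks at precursor + k * 1.006277 Da
(the H->D mass step; the accepted per-step window is 1.0063 +/- 0.0002).
Because the instrument merges the 2H shift with the natural 13C/15N/18O
shifts, the observed ladder is the convolution of the true deuterium-count
distribution with the ion's natural isotope pattern; `natural_correction`
inverts that convolution by forward substitution to recover the deuterium
distribution, from which deuterated channels are flagged and the number of
exchangeable proton sites is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_core import Adduct, DEUTERIUM_STEP, Formula, natural_pattern
from .hdx_forward_model import DeuteriumDistribution, DeuteriumLadder
from .spectrum_io import Spectrum

__all__ = [
    "STEP_TOLERANCE",
    "LadderNotFoundError",
    "LadderJudgment",
    "find_ladder",
    "natural_correction",
    "judge_deuteration",
    "base_peak_index",
    "rank_by_deuteration",
]

#: Accepted deviation of a single deuteration mass shift from 1.006277 Da.
STEP_TOLERANCE = 0.0002


class LadderNotFoundError(ValueError):
    pass


@dataclass(frozen=True)
class LadderJudgment:
    """Per-channel deuteration call after natural-isotope correction."""

    corrected: DeuteriumDistribution
    is_deuterated: tuple[bool, ...]
    site_count_estimate: int

    @property
    def flagged_channels(self) -> tuple[int, ...]:
        return tuple(k for k, f in enumerate(self.is_deuterated) if f)

    @property
    def n_deuterium_peaks(self) -> int:
        """Number of deuterated channels (k >= 1)."""
        return sum(self.is_deuterated[1:])


def find_ladder(
    spectrum: Spectrum,
    precursor_mz: float,
    max_k: int = 10,
    step_tol: float = STEP_TOLERANCE,
    precursor_tol: float = 0.002,
) -> DeuteriumLadder:
    """Extract the deuterium ladder of ``precursor_mz`` from a spectrum.

    Channel k is searched at matched_precursor + k * 1.006277 within the
    accumulated window k * step_tol (each step contributes its own error);
    missing channels are recorded as zero intensity.  The precursor itself
    must be present within ``precursor_tol`` (instrument peak width).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    mz, inten = spectrum.mz, spectrum.intensity
    i0 = _nearest_peak(mz, precursor_mz, precursor_tol)
    if i0 is None:
        raise LadderNotFoundError(
            f"no peak within {precursor_tol} Da of precursor m/z {precursor_mz:.4f}"
        )
    anchor = mz[i0]
    channels = np.zeros(max_k + 1)
    channels[0] = inten[i0]
    for k in range(1, max_k + 1):
        idx = _nearest_peak(mz, anchor + k * DEUTERIUM_STEP, k * step_tol)
        if idx is not None:
            channels[k] = inten[idx]
    last = int(np.nonzero(channels)[0][-1])
    return DeuteriumLadder(anchor, channels[: last + 1])


def _nearest_peak(mz: np.ndarray, target: float, tol: float) -> int | None:
    i = int(np.searchsorted(mz, target))
    best, best_err = None, tol
    for j in (i - 1, i):
        if 0 <= j < len(mz):
            err = abs(mz[j] - target)
            if err <= best_err:
                best, best_err = j, err
    return best


def natural_correction(
    ladder: DeuteriumLadder, formula: Formula, adduct: Adduct
) -> DeuteriumDistribution:
    """Recover the deuterium-count distribution from an observed ladder.

    Solves the lower-triangular system I(k) = sum_{d<=k} pmf(d) * nat(k-d)
    by forward substitution.  Noise can push components negative; they are
    clipped to zero and the result renormalized, the standard treatment in
    isotope-enrichment correction.
    """
    nat = natural_pattern(formula * adduct.multimer, len(ladder.intensities)).abundances
    if nat[0] <= 0:
        raise ValueError("singular correction: zero monoisotopic abundance")
    obs = ladder.intensities.astype(float)
    pmf = np.zeros_like(obs)
    for k in range(len(obs)):
        acc = obs[k] - sum(pmf[d] * nat[k - d] for d in range(k))
        pmf[k] = acc / nat[0]
    pmf = np.clip(pmf, 0.0, None)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("corrected distribution vanished")
    return DeuteriumDistribution(pmf / total)


def judge_deuteration(
    ladder: DeuteriumLadder,
    formula: Formula,
    adduct: Adduct,
    excess_threshold: float = 1.0,
    charge_site_assumed: bool = True,
) -> LadderJudgment:
    """Flag deuterated channels and estimate the exchangeable-site count.

    Channel k >= 1 is called deuterated when its corrected deuterium mass is
    at least ``excess_threshold`` percent of the largest corrected channel
    (default 1% of the base of the corrected distribution).  The site-count
    estimate is the highest flagged channel minus one charge-site deuteron
    when the adduct is proton-bearing and charge-site exchange is assumed.
    """
    if excess_threshold < 0:
        raise ValueError("threshold must be non-negative")
    corrected = natural_correction(ladder, formula, adduct)
    pmf = corrected.pmf
    cut = (excess_threshold / 100.0) * pmf.max()
    flags = [False] + [bool(pmf[k] >= cut and pmf[k] > 0) for k in range(1, len(pmf))]
    flagged = [k for k, f in enumerate(flags) if f]
    max_k = max(flagged) if flagged else 0
    charge_extra = 1 if (adduct.proton_bearing and charge_site_assumed) else 0
    return LadderJudgment(
        corrected, tuple(flags), max(0, max_k - charge_extra)
    )


def base_peak_index(ladder: DeuteriumLadder) -> int:
    """Channel of the most intense peak; ties break toward smaller k."""
    if len(ladder.intensities) == 0:
        raise ValueError("empty ladder")
    return int(np.argmax(ladder.intensities))


def rank_by_deuteration(
    spectrum: Spectrum,
    candidates: list[tuple[float, Formula, Adduct]],
    top_n: int = 10,
    max_k: int = 10,
    excess_threshold: float = 1.0,
) -> list[tuple[float, LadderJudgment]]:
    """Rank candidate precursors by how strongly they exchanged.

    Candidates are ordered by number of flagged deuterium channels, ties by
    total corrected deuterium mass (sum over k >= 1), then by m/z ascending;
    the ``top_n`` strongest are returned as (precursor_mz, judgment) pairs.
    Candidates whose precursor is absent from the spectrum are dropped.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scored = []
    for mz, formula, adduct in candidates:
        try:
            ladder = find_ladder(spectrum, mz, max_k=max_k)
        except LadderNotFoundError:
            continue
        j = judge_deuteration(ladder, formula, adduct, excess_threshold)
        d_mass = float(j.corrected.pmf[1:].sum())
        scored.append(((-j.n_deuterium_peaks, -d_mass, mz), mz, j))
    scored.sort(key=lambda t: t[0])
    return [(mz, j) for _, mz, j in scored[:top_n]]
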