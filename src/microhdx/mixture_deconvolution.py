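"""Two-component isobaric mixture model and its L1 pattern loss.

A mixed HDX pattern of two isobaric ions is modeled as a linear combination
of the two pure patterns weighted by molar amount,

    I_abs(k) = N_g * I_g(k) + N_i * I_i(k),

valid under the explicit assumption that the two ions have (very nearly)
equal ionization efficiencies, so that per-mole pattern scales are
commensurate.  Patterns are compared after base-peak normalization
(I_rel = 100 * I_abs / I_BP) with the mean absolute deviation over the
common channel range,

    Loss = 1/(n+1) * sum_{k=0..n} |I_sim(k) - I_obs(k)|   [% units],

and the molar composition is estimated by minimizing that loss over the
mole-fraction simplex.  The objective is piecewise linear in the fraction,
so the minimizer is found by a deterministic grid search at 1e-3 resolution
followed by a local 1e-5 refinement rather than by smooth optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hdx_forward_model import DeuteriumLadder

__all__ = [
    "MixtureComposition",
    "PatternFit",
    "mix_patterns",
    "to_relative",
    "pattern_loss",
    "estimate_composition",
]


@dataclass(frozen=True)
class MixtureComposition:
    """Molar amounts of the two isobaric components (arbitrary molar units)."""

    n_g: float
    n_i: float

    def __post_init__(self) -> None:
        if self.n_g < 0 or self.n_i < 0 or self.n_g + self.n_i <= 0:
            raise ValueError("molar amounts must be >= 0 with positive total")

    @property
    def fractions(self) -> tuple[float, float]:
        total = self.n_g + self.n_i
        return self.n_g / total, self.n_i / total


@dataclass(frozen=True)
class PatternFit:
    composition: MixtureComposition
    fitted_relative: np.ndarray
    loss: float
    n_channels: int


def _pad_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = max(len(a), len(b))
    return (
        np.pad(np.asarray(a, float), (0, n - len(a))),
        np.pad(np.asarray(b, float), (0, n - len(b))),
    )


def mix_patterns(
    pure_g: DeuteriumLadder,
    pure_i: DeuteriumLadder,
    comp: MixtureComposition,
    mz_tol: float = 0.01,
) -> DeuteriumLadder:
    """Channel-wise linear combination of two pure isobaric ladders.

    Both ladders must share the precursor m/z (isobaric pair) and be on a
    common per-mole intensity scale — i.e. equal ionization efficiencies are
    assumed; the shorter ladder is zero-padded.
    """
    if abs(pure_g.precursor_mz - pure_i.precursor_mz) > mz_tol:
        raise ValueError(
            "precursor mismatch: "
            f"{pure_g.precursor_mz:.4f} vs {pure_i.precursor_mz:.4f} (not isobaric)"
        )
    g, i = _pad_pair(pure_g.intensities, pure_i.intensities)
    return DeuteriumLadder(
        pure_g.precursor_mz,
        comp.n_g * g + comp.n_i * i,
        f"{pure_g.compound}+{pure_i.compound}",
    )


def to_relative(pattern: np.ndarray | DeuteriumLadder) -> np.ndarray:
    """Base-peak-normalized pattern: max channel = 100."""
    arr = pattern.intensities if isinstance(pattern, DeuteriumLadder) else pattern
    arr = np.asarray(arr, dtype=float)
    bp = arr.max()
    if bp <= 0:
        raise ValueError("cannot normalize an all-zero pattern")
    return 100.0 * arr / bp


def pattern_loss(sim: np.ndarray, obs: np.ndarray) -> float:
    """Mean absolute deviation between two relative patterns, in % units."""
    s, o = _pad_pair(sim, obs)
    return float(np.abs(s - o).mean())


def estimate_composition(
    obs_relative: np.ndarray,
    pure_g: DeuteriumLadder,
    pure_i: DeuteriumLadder,
    grid: float = 1e-3,
    refine: float = 1e-5,
) -> PatternFit:
    """Best-fit mole fractions of an observed relative pattern.

    Minimizes the L1 pattern loss over mole fraction f in [0, 1] where the
    simulated pattern is f * pure_g + (1-f) * pure_i (per-mole pure patterns),
    base-peak normalized.  Deterministic: coarse grid then local refinement.
    """
    g, i = _pad_pair(pure_g.intensities, pure_i.intensities)
    if g.max() <= 0 or i.max() <= 0:
        raise ValueError("pure patterns must be non-zero")
    # per-mole scale: unit total intensity per component
    g, i = g / g.sum(), i / i.sum()
    if pattern_loss(to_relative(g), to_relative(i)) < 1e-9:
        raise ValueError("pure patterns are collinear: composition not identifiable")
    rel = to_relative(np.asarray(obs_relative, float))
    obs_padded, _ = _pad_pair(rel, g)

    def loss_at(f: float) -> float:
        return pattern_loss(to_relative(f * g + (1 - f) * i), obs_padded)

    fs = np.arange(0.0, 1.0 + grid / 2, grid)
    losses = np.array([loss_at(f) for f in fs])
    f_best = float(fs[int(np.argmin(losses))])
    lo, hi = max(0.0, f_best - grid), min(1.0, f_best + grid)
    fine = np.arange(lo, hi + refine / 2, refine)
    fine_losses = np.array([loss_at(f) for f in fine])
    f_best = float(fine[int(np.argmin(fine_losses))])
    best = float(fine_losses.min())
    comp = MixtureComposition(f_best, 1.0 - f_best)
    return PatternFit(
        comp, to_relative(f_best * g + (1 - f_best) * i), best, len(g)
    )
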