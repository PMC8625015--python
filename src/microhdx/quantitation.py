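"""Absolute quantitation of one isobaric component via its signature channel.

When two isobaric ions overlap, the target can still be quantified from a
deuterium channel that only it populates (e.g. codeine's D2 over hydrocodone,
which reaches only D1).  The response is the absolute intensity of that
signature channel ratioed to an internal-standard channel — ratioing to the
IS removes run-to-run scale, so base-peak renormalization is deliberately
NOT applied here (it would distort linearity).  A six-point series then
yields an ordinary least-squares calibration line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hdx_forward_model import DeuteriumLadder
from .ladder_detection import LadderJudgment

__all__ = [
    "CalibrationCurve",
    "NoSignatureError",
    "signature_channel",
    "internal_standard_response",
    "fit_calibration",
    "quantify",
]


class NoSignatureError(ValueError):
    """No deuterium channel separates target from interferent."""


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    pearson_r: float
    points: tuple[tuple[float, float], ...]
    concentration_units: str = "ug/mL"

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration


def signature_channel(target: LadderJudgment, interferent: LadderJudgment) -> int:
    """Smallest channel flagged for the target but not for the interferent.

    Asymmetric by construction: the signature of A over B is generally not
    the signature of B over A (and may not exist at all).
    """
    t_flags = set(target.flagged_channels)
    i_flags = set(interferent.flagged_channels)
    unique = sorted(t_flags - i_flags)
    if not unique:
        raise NoSignatureError(
            "target has no deuterium channel free of interferent overlap"
        )
    return unique[0]


def internal_standard_response(
    target_ladder: DeuteriumLadder,
    channel: int,
    is_ladder: DeuteriumLadder,
    is_channel: int | None = None,
) -> float:
    """Response = I(signature channel of target) / I(IS channel), on absolute
    intensities.  The IS channel defaults to the IS ladder's base peak (its
    strongest channel is the stable choice)."""
    if is_channel is None:
        is_channel = int(np.argmax(is_ladder.intensities))
    denom = is_ladder.intensities[is_channel]
    if denom <= 0:
        raise ValueError("internal-standard channel has zero intensity")
    return float(target_ladder.intensities[channel] / denom)


def fit_calibration(
    points: list[tuple[float, float]], units: str = "ug/mL"
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, response) points."""
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in points], dtype=float)
    resp = np.array([p[1] for p in points], dtype=float)
    if len(set(conc.tolist())) < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    if np.var(conc) == 0:
        raise ValueError("zero concentration variance")
    fit = stats.linregress(conc, resp)
    return CalibrationCurve(
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue),
        tuple((float(c), float(r)) for c, r in points),
        units,
    )


def quantify(response: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Inverse prediction (response - intercept) / slope.

    Returns (concentration, below_range): negative inverse predictions are
    reported as-is with the below-range flag set rather than clipped.
    """
    if curve.slope == 0:
        raise ValueError("zero calibration slope")
    conc = (response - curve.intercept) / curve.slope
    return float(conc), conc < 0
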