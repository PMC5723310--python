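"""Deterministic H2B-GFP label-dilution kinetics.

In a tet-inducible H2B-GFP pulse-chase experiment, nuclear label intensity
falls by a factor of two at each cell division (the histone pool is split
between daughters) and additionally decays exponentially through protein
turnover.  With a half-life ``T`` (days), a cell that started the chase at
intensity ``I0`` and has undergone ``d`` divisions after ``t`` days carries

    I(d, t) = I0 * 2**(-d) * 2**(-t / T)

All times are in days (16 weeks == 112 days); intensities are arbitrary
fluorescence units.  The functions here derive gating thresholds and
division bounds from this model; they are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LabelDecayParams",
    "CellLabelState",
    "intensity_after",
    "fold_dilution",
    "min_divisions_below",
    "gfphi_model_threshold",
]

#: Default measurement-spread allowance for the model-derived GFPhi gate:
#: half a division on the log2 scale, i.e. sqrt(2).
DEFAULT_GFPHI_ALLOWANCE: float = math.sqrt(2.0)


@dataclass(frozen=True)
class LabelDecayParams:
    """Parameters of the label-decay model.

    Parameters
    ----------
    half_life_days
        Half-life of the H2B-GFP protein, days.  Default 24.
    pulse_intensity_I0
        Fluorescence at the end of the labeling pulse, arbitrary units.
    chase_days
        Length of the chase period, days.  Default 112 (16 weeks).
    """

    half_life_days: float = 24.0
    pulse_intensity_I0: float = 1000.0
    chase_days: float = 112.0

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half_life_days must be > 0")
        if self.pulse_intensity_I0 <= 0:
            raise ValueError("pulse_intensity_I0 must be > 0")
        if self.chase_days < 0:
            raise ValueError("chase_days must be >= 0")


@dataclass(frozen=True)
class CellLabelState:
    """Model state of a single labeled cell during the chase."""

    divisions: int
    time_since_pulse: float
    intensity: float

    @classmethod
    def evolve(
        cls, divisions: int, time_since_pulse: float, params: LabelDecayParams
    ) -> "CellLabelState":
        """State of a cell after ``divisions`` divisions and ``time_since_pulse`` days."""
        return cls(
            divisions=divisions,
            time_since_pulse=time_since_pulse,
            intensity=intensity_after(
                params.pulse_intensity_I0, divisions, time_since_pulse, params
            ),
        )


def intensity_after(
    I0: float, divisions: int, elapsed: float, params: LabelDecayParams | None = None
) -> float:
    """Label intensity after ``divisions`` divisions and ``elapsed`` days of turnover.

    Returns ``I0 * 2**(-divisions) * 2**(-elapsed / half_life)``; strictly
    decreasing in both ``divisions`` and ``elapsed``.
    """
    if params is None:
        params = LabelDecayParams()
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    if divisions < 0:
        raise ValueError("divisions must be >= 0")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return I0 * 2.0 ** (-float(divisions)) * 2.0 ** (-elapsed / params.half_life_days)


def fold_dilution(divisions: int) -> float:
    """Division-only dilution factor: ``2**divisions`` (3 divisions -> eightfold)."""
    if divisions < 0:
        raise ValueError("divisions must be >= 0")
    return 2.0**divisions


def min_divisions_below(ratio_to_boundary: float) -> int:
    """Smallest division count taking a cell strictly below the GFP- boundary.

    ``ratio_to_boundary`` is the current intensity expressed as a multiple of
    the GFP-/GFPint boundary.  Returns the smallest integer ``d`` with
    ``ratio * 2**(-d) < 1`` — strictly below: a cell sitting exactly at the
    boundary is still not GFP-, so a 4x margin requires three divisions
    (an eightfold dilution), not two.
    """
    if ratio_to_boundary <= 0:
        raise ValueError("ratio_to_boundary must be > 0")
    if ratio_to_boundary < 1:
        return 0
    d = math.floor(math.log2(ratio_to_boundary)) + 1
    # guard against floating-point drift near exact powers of two
    while ratio_to_boundary * 2.0 ** (-d) >= 1.0:
        d += 1
    while d > 0 and ratio_to_boundary * 2.0 ** (-(d - 1)) < 1.0:
        d -= 1
    return d


def gfphi_model_threshold(
    params: LabelDecayParams, allowance: float = DEFAULT_GFPHI_ALLOWANCE
) -> float:
    """Model-derived GFPhi gate: lowest intensity consistent with zero divisions.

    A cell that never divided ends the chase at
    ``intensity_after(I0, 0, chase_days)``; dividing that by ``allowance``
    (>= 1) leaves room for measurement spread below the zero-division line.
    The default allowance of sqrt(2) is half a division on the log2 scale,
    placing the gate symmetrically between zero- and one-division cells.
    """
    if allowance < 1:
        raise ValueError("allowance must be >= 1")
    return intensity_after(params.pulse_intensity_I0, 0, params.chase_days, params) / allowance
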