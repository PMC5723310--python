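"""GFP gating: classify flow events into GFP-/GFPint/GFPhi and summarize LRCs.

Two thresholds define the classes.  The negative boundary separates events
indistinguishable from the negative control from partially diluted
(GFPint) cells; it is estimated from the control table as an upper quantile
(99.9th percentile by default).  The GFPhi boundary separates
label-retaining cells — cells whose intensity is consistent with zero
divisions over the chase — from GFPint; by default it is the larger of the
kinetics-model threshold and four times the negative boundary, so the GFPhi
gate always keeps at least a 4x margin over the control (three divisions,
an eightfold dilution, to fall from the gate to GFP-).

Boundary conventions (fixed, documented): an event exactly at the negative
boundary is GFP-; an event exactly at the GFPhi boundary is GFPhi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, UndefinedStatisticError
from .kinetics import DEFAULT_GFPHI_ALLOWANCE, LabelDecayParams, gfphi_model_threshold

__all__ = [
    "GateThresholds",
    "GateResult",
    "estimate_neg_boundary",
    "derive_thresholds",
    "classify_events",
    "lrc_frequency",
    "lrc_composition",
    "GFP_NEG",
    "GFP_INT",
    "GFP_HI",
]

GFP_NEG = "GFPneg"
GFP_INT = "GFPint"
GFP_HI = "GFPhi"
MARGIN = 4.0  # minimum GFPhi/neg-boundary ratio


@dataclass(frozen=True)
class GateThresholds:
    """The two gate positions, in fluorescence units."""

    neg_boundary: float
    gfphi_boundary: float

    def __post_init__(self) -> None:
        if self.neg_boundary <= 0 or self.gfphi_boundary <= 0:
            raise ConfigError("thresholds must be > 0")
        if self.gfphi_boundary < MARGIN * self.neg_boundary:
            raise ConfigError(
                f"gfphi_boundary must be at least {MARGIN:.0f}x neg_boundary "
                f"(got {self.gfphi_boundary:.4g} < {MARGIN:.0f} * {self.neg_boundary:.4g})"
            )


@dataclass
class GateResult:
    """Per-event classes plus the thresholds and per-subset frequency table."""

    classes: pd.Series
    thresholds: GateThresholds
    frequencies: pd.DataFrame  # index: subset; columns: GFPneg/GFPint/GFPhi fractions

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "neg_boundary": self.thresholds.neg_boundary,
                "gfphi_boundary": self.thresholds.gfphi_boundary,
            },
            "frequencies": self.frequencies.to_dict(orient="index"),
        }


def estimate_neg_boundary(
    control: pd.DataFrame, quantile: float = 0.999, rule: str = "quantile"
) -> float:
    """Negative boundary from the control table.

    ``rule='quantile'`` returns the given upper quantile of control
    intensities (linear interpolation); ``rule='max'`` returns their maximum.
    """
    if len(control) == 0:
        raise InputError("control table is empty")
    x = np.asarray(control["intensity"], dtype=float)
    if rule == "max":
        return float(x.max())
    if rule != "quantile":
        raise ConfigError(f"unknown rule {rule!r}")
    if not 0 < quantile <= 1:
        raise ConfigError("quantile must lie in (0, 1]")
    return float(np.quantile(x, quantile))


def derive_thresholds(
    control: pd.DataFrame,
    decay: LabelDecayParams,
    allowance: float = DEFAULT_GFPHI_ALLOWANCE,
    quantile: float = 0.999,
) -> GateThresholds:
    """Default gate: empirical negative boundary + model-derived GFPhi gate.

    The GFPhi boundary is ``max(model threshold, 4 * neg_boundary)`` so the
    half-life-aware gate never undercuts the 4x control margin.
    """
    neg = estimate_neg_boundary(control, quantile=quantile)
    model = gfphi_model_threshold(decay, allowance)
    return GateThresholds(neg_boundary=neg, gfphi_boundary=max(model, MARGIN * neg))


def classify_events(events: pd.DataFrame, thresholds: GateThresholds) -> GateResult:
    """Classify every event and tabulate per-subset class frequencies.

    ``intensity <= neg_boundary`` -> GFP-; ``intensity >= gfphi_boundary``
    -> GFPhi; strictly between -> GFPint.  Classification is monotone in
    intensity.
    """
    intensity = np.asarray(events["intensity"], dtype=float)
    classes = np.where(
        intensity <= thresholds.neg_boundary,
        GFP_NEG,
        np.where(intensity >= thresholds.gfphi_boundary, GFP_HI, GFP_INT),
    )
    class_series = pd.Series(classes, index=events.index, name="gfp_class")
    freq = (
        pd.crosstab(events["subset"], class_series, normalize="index")
        .reindex(columns=[GFP_NEG, GFP_INT, GFP_HI], fill_value=0.0)
    )
    freq.columns.name = None
    return GateResult(classes=class_series, thresholds=thresholds, frequencies=freq)


def lrc_frequency(result: GateResult, subset: str) -> float:
    """Percentage of events in ``subset`` called GFPhi (i.e. LRCs)."""
    if subset not in result.frequencies.index:
        raise InputError(f"unknown subset {subset!r}")
    return 100.0 * float(result.frequencies.loc[subset, GFP_HI])


def lrc_composition(f_minus: float, f_plus: float, p_minus: float) -> float:
    """Fraction of all LRCs that belong to the UEA1- subset.

    Combines per-subset LRC frequencies with the population composition:
    ``f_minus * p_minus / (f_minus * p_minus + f_plus * (1 - p_minus))``.
    Scale-invariant in ``(f_minus, f_plus)``.
    """
    if not (0 <= f_minus <= 1 and 0 <= f_plus <= 1 and 0 <= p_minus <= 1):
        raise InputError("frequencies and population fraction must lie in [0, 1]")
    num = f_minus * p_minus
    den = num + f_plus * (1.0 - p_minus)
    if den == 0:
        raise UndefinedStatisticError("no LRCs in either subset: composition undefined")
    return num / den
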