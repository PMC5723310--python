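"""BrdU proliferation analysis.

BrdU (bromodeoxyuridine) is incorporated during DNA replication, so the
BrdU+ fraction of a cell group measures its proliferative activity over the
labeling window.  The central quantity is the proliferation index, the
ratio of BrdU+ fractions between the regeneration timepoint (day 7 after
sublethal irradiation) and the unirradiated baseline (day 0).  For these
analyses GFP+ means GFPhi or GFPint combined (the progeny of a
label-retaining cell after one or two divisions is still GFP+), collapsed
against GFP-.

A median-fluorescence check guards against BrdU signal arising from DNA
repair rather than replication: replicating cells incorporate far more
BrdU, so the BrdU+ median should exceed the whole-population median by a
large factor (7x by default).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "brdu_fraction",
    "proliferation_index",
    "mfi_ratio",
    "subset_change",
    "ProliferationReport",
    "proliferation_report",
]


def _group(
    records: pd.DataFrame, subset: str, gfp_class: str, timepoint: str
) -> pd.DataFrame:
    sel = (
        (records["subset"] == subset)
        & (records["gfp_class"] == gfp_class)
        & (records["timepoint"] == timepoint)
    )
    return records[sel]


def brdu_fraction(
    records: pd.DataFrame, subset: str, gfp_class: str, timepoint: str
) -> float:
    """BrdU+ fraction within one (subset, GFP class, timepoint) group."""
    g = _group(records, subset, gfp_class, timepoint)
    if len(g) == 0:
        raise InputError(f"no records for ({subset}, {gfp_class}, {timepoint})")
    return float(np.asarray(g["brdu"], dtype=bool).mean())


def proliferation_index(frac_day7: float, frac_day0: float) -> float:
    """Day-7 over day-0 BrdU+ fraction ratio; undefined on a zero baseline."""
    if not (0 <= frac_day7 <= 1 and 0 <= frac_day0 <= 1):
        raise InputError("fractions must lie in [0, 1]")
    if frac_day0 == 0:
        raise UndefinedStatisticError("day-0 BrdU fraction is 0: index undefined")
    return frac_day7 / frac_day0


def mfi_ratio(
    records: pd.DataFrame, timepoint: str, replication_factor: float = 7.0
) -> tuple[float, bool]:
    """Median BrdU fluorescence of BrdU+ cells over the whole population.

    Returns ``(ratio, consistent_with_replication)`` where the flag is True
    when the ratio exceeds ``replication_factor``.
    """
    at_tp = records[records["timepoint"] == timepoint]
    pos = at_tp[at_tp["brdu"].astype(bool)]
    if len(at_tp) == 0 or len(pos) == 0:
        raise InputError(f"no (BrdU+) records at {timepoint!r}")
    pop_median = float(at_tp["intensity_brdu"].median())
    if pop_median == 0:
        raise UndefinedStatisticError("whole-population median is 0: ratio undefined")
    ratio = float(pos["intensity_brdu"].median()) / pop_median
    return ratio, ratio > replication_factor


def subset_change(count_day0: float, count_day7: float) -> float:
    """Fold-change in subset cellularity, day 7 over day 0."""
    if count_day0 <= 0:
        raise UndefinedStatisticError("day-0 count must be > 0")
    return count_day7 / count_day0


@dataclass(frozen=True)
class GroupKinetics:
    brdu_fraction_day0: float
    brdu_fraction_day7: float
    proliferation_index: float | None  # None when the day-0 baseline is 0


@dataclass
class ProliferationReport:
    """Per-group BrdU fractions and indices plus the MFI replication check."""

    groups: dict[str, GroupKinetics]
    mfi_ratio_day0: float
    mfi_ratio_day7: float
    mfi_consistent_day0: bool
    mfi_consistent_day7: bool

    def to_dict(self) -> dict:
        return {
            "groups": {k: asdict(v) for k, v in self.groups.items()},
            "mfi_ratio": {"day0": self.mfi_ratio_day0, "day7": self.mfi_ratio_day7},
            "mfi_consistent_with_replication": {
                "day0": self.mfi_consistent_day0,
                "day7": self.mfi_consistent_day7,
            },
        }


def proliferation_report(
    records: pd.DataFrame, replication_factor: float = 7.0
) -> ProliferationReport:
    """Compute fractions, indices and MFI checks for every group in the table."""
    groups: dict[str, GroupKinetics] = {}
    for subset in sorted(records["subset"].unique()):
        for gfp_class in sorted(records["gfp_class"].unique()):
            f0 = brdu_fraction(records, subset, gfp_class, "day0")
            f7 = brdu_fraction(records, subset, gfp_class, "day7")
            index = proliferation_index(f7, f0) if f0 > 0 else None
            groups[f"{subset}/{gfp_class}"] = GroupKinetics(f0, f7, index)
    r0, ok0 = mfi_ratio(records, "day0", replication_factor)
    r7, ok7 = mfi_ratio(records, "day7", replication_factor)
    return ProliferationReport(
        groups=groups,
        mfi_ratio_day0=r0,
        mfi_ratio_day7=r7,
        mfi_consistent_day0=ok0,
        mfi_consistent_day7=ok7,
    )
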