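"""Spatial statistics for label-retaining-cell (LRC) point patterns.

Covers the quantitative treatment of LRC positions in thymic sections:

* region assignment (cortex / medulla / cortico-medullary region, the CMR
  being the band within ``halfwidth_um`` of the cortico-medullary junction),
* quadrat partitioning into equal-area sections and per-section counts,
* the dispersion index (variance-to-mean ratio; 1 under complete spatial
  randomness, > 1 for clustered patterns),
* a chi-square goodness-of-fit test of the maximum-likelihood Poisson model,
  with a likelihood-ratio-style dispersion test as an alternative,
* cluster summaries (fraction of cells in high-count sections),
* compartment enrichment ratios (count share over area share), and
* the microscopy LRC-calling rule (4x the brightest negative-control cell).

Counts are plain integer arrays; tissue geometry travels as a
:class:`TissueMap` (label masks at a known pixel size plus a point set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, stats

from .errors import ConfigError, InputError, UndefinedStatisticError

__all__ = [
    "TissueMap",
    "QuadratGrid",
    "DispersionReport",
    "REGION_CORTEX",
    "REGION_MEDULLA",
    "REGION_CMR",
    "COMPARTMENT_LABELS",
    "assign_region",
    "quadrat_partition",
    "assign_compartment",
    "dispersion_index",
    "poisson_gof",
    "dispersion_test",
    "cluster_summary",
    "compartment_enrichment",
    "image_lrc_threshold",
]

P_VALUE_FLOOR = 2.2e-16

REGION_CORTEX = "cortex"
REGION_MEDULLA = "medulla"
REGION_CMR = "CMR"

#: Compartment mask encoding: 0 = background, then cytokeratin classes.
COMPARTMENT_LABELS: dict[int, str] = {0: "background", 1: "K5", 2: "K8", 3: "K5K8"}


@dataclass
class TissueMap:
    """A 2-D tissue section: label masks plus an LRC point pattern.

    Attributes
    ----------
    points
        ``(n, 2)`` array of LRC positions, columns ``(x_um, y_um)``.
    medulla
        Boolean mask ``(H, W)``; True inside the medulla.
    compartments
        ``uint8`` label mask ``(H, W)`` encoded per :data:`COMPARTMENT_LABELS`.
    tissue
        Boolean footprint mask; False pixels are background.
    pixel_size_um
        Edge length of one mask pixel in micrometres.
    """

    points: np.ndarray
    medulla: np.ndarray
    compartments: np.ndarray
    tissue: np.ndarray
    pixel_size_um: float = 1.0
    _cmj_distance: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.medulla.shape != self.compartments.shape or self.medulla.shape != self.tissue.shape:
            raise ConfigError("medulla, compartments and tissue masks must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.medulla.shape

    def cmj_distance_um(self) -> np.ndarray:
        """Per-pixel Euclidean distance to the cortico-medullary junction.

        The CMJ is the cortex/medulla interface.  Distances are computed with
        a Euclidean distance transform on each side of the interface and
        corrected by half a pixel so that pixels touching the boundary read
        (close to) zero.  Cached after the first call.
        """
        if self._cmj_distance is None:
            med = self.medulla & self.tissue
            cor = (~self.medulla) & self.tissue
            d_from_med = ndimage.distance_transform_edt(~med)
            d_from_cor = ndimage.distance_transform_edt(~cor)
            d = np.where(med, d_from_cor, d_from_med)
            self._cmj_distance = np.clip(d - 0.5, 0.0, None) * self.pixel_size_um
        return self._cmj_distance

    def cmj_distance_at(self, points: np.ndarray) -> np.ndarray:
        """CMJ distance at arbitrary (x_um, y_um) positions.

        Bilinear interpolation of the pixel-center distance field, so a point
        exactly ``d`` micrometres from a straight boundary reads ``d`` rather
        than the distance of its pixel center.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        coords = np.stack(
            [pts[:, 1] / self.pixel_size_um - 0.5, pts[:, 0] / self.pixel_size_um - 0.5]
        )
        return ndimage.map_coordinates(
            self.cmj_distance_um(), coords, order=1, mode="nearest"
        )

    def pixel_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (x_um, y_um) positions to (row, col) mask indices, clipped to bounds."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        col = np.clip((pts[:, 0] / self.pixel_size_um).astype(int), 0, self.shape[1] - 1)
        row = np.clip((pts[:, 1] / self.pixel_size_um).astype(int), 0, self.shape[0] - 1)
        return row, col


@dataclass(frozen=True)
class QuadratGrid:
    """An r x c grid of half-open, equal-area rectangular sections.

    Sections are ``[x0, x1) x [y0, y1)`` in micrometres; ``n_sections = rows * cols``.
    """

    rows: int
    cols: int
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n_sections(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class DispersionReport:
    """Summary of a quadrat-count dispersion analysis."""

    n: int
    mean: float
    variance: float
    dispersion_index: float
    gof_statistic: float
    gof_df: int
    gof_p: float


def assign_region(
    points: np.ndarray, tissue_map: TissueMap, halfwidth_um: float = 100.0
) -> np.ndarray:
    """Assign each point to cortex, medulla, or the cortico-medullary region.

    A point whose Euclidean distance to the CMJ is at most ``halfwidth_um``
    (boundary inclusive) lies in the CMR; otherwise it is medulla or cortex
    according to the label mask under it.  Points on background raise
    :class:`InputError`.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = tissue_map.pixel_index(pts)
    if not np.all(tissue_map.tissue[row, col]):
        bad = int(np.flatnonzero(~tissue_map.tissue[row, col])[0])
        raise InputError(f"point {bad} at {tuple(pts[bad])} lies outside the tissue footprint")
    dist = tissue_map.cmj_distance_at(pts)
    regions = np.where(
        dist <= halfwidth_um,
        REGION_CMR,
        np.where(tissue_map.medulla[row, col], REGION_MEDULLA, REGION_CORTEX),
    )
    return regions


def assign_compartment(points: np.ndarray, tissue_map: TissueMap) -> np.ndarray:
    """Cytokeratin compartment (K5 / K8 / K5K8) of the mask pixel under each point."""
    row, col = tissue_map.pixel_index(points)
    labels = tissue_map.compartments[row, col]
    if np.any(labels == 0):
        bad = int(np.flatnonzero(labels == 0)[0])
        raise InputError(f"point {bad} lies on background")
    return np.array([COMPARTMENT_LABELS[int(v)] for v in labels])


def _near_square_grid(n: int) -> tuple[int, int]:
    """Factor n into rows x cols as close to square as possible."""
    best = (1, n)
    for r in range(1, int(math.isqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def quadrat_partition(
    tissue_map: TissueMap, target_sections: int = 45
) -> tuple[QuadratGrid, np.ndarray]:
    """Partition the tissue bounding box into equal-area sections and count points.

    The grid is the near-square factorization of ``target_sections`` laid over
    the mask bounding box; sections are half-open rectangles so every point
    falls in exactly one section and counts always sum to the point total.
    """
    if target_sections < 2:
        raise ConfigError("target_sections must be >= 2")
    h, w = tissue_map.shape
    width_um = w * tissue_map.pixel_size_um
    height_um = h * tissue_map.pixel_size_um
    rows, cols = _near_square_grid(target_sections)
    if height_um < width_um and rows < cols:
        rows, cols = cols, rows
    x_edges = np.linspace(0.0, width_um, cols + 1)
    y_edges = np.linspace(0.0, height_um, rows + 1)
    grid = QuadratGrid(rows=rows, cols=cols, x_edges=x_edges, y_edges=y_edges)
    pts = tissue_map.points
    if pts.size == 0:
        return grid, np.zeros(target_sections, dtype=int)
    ci = np.minimum((pts[:, 0] / width_um * cols).astype(int), cols - 1)
    ri = np.minimum((pts[:, 1] / height_um * rows).astype(int), rows - 1)
    counts = np.bincount(ri * cols + ci, minlength=target_sections)
    return grid, counts


def dispersion_index(counts: np.ndarray) -> float:
    """Variance-to-mean ratio of quadrat counts (sample variance, n-1 denominator)."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise InputError("need at least 2 sections")
    mean = c.mean()
    if mean == 0:
        raise UndefinedStatisticError("dispersion index undefined for zero mean")
    return float(c.var(ddof=1) / mean)


def _merged_poisson_bins(
    counts: np.ndarray, lam: float, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram bins over the integer support with every expected cell >= min_expected.

    Adjacent integer cells are merged greedily from the low end; the final bin
    absorbs the upper tail (expected mass from the survival function) and is
    merged backwards if still short.
    """
    n = counts.size
    kmax = int(counts.max())
    support = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(support, lam)
    observed_by_k = np.bincount(counts.astype(int), minlength=kmax + 1).astype(float)

    obs_bins: list[float] = []
    exp_bins: list[float] = []
    acc_obs = 0.0
    acc_exp = 0.0
    for k in support:
        acc_obs += observed_by_k[k]
        acc_exp += n * pmf[k]
        if acc_exp >= min_expected:
            obs_bins.append(acc_obs)
            exp_bins.append(acc_exp)
            acc_obs = 0.0
            acc_exp = 0.0
    # open upper tail beyond kmax plus any unflushed cells
    tail_exp = acc_exp + n * stats.poisson.sf(kmax, lam)
    tail_obs = acc_obs
    if exp_bins and tail_exp < min_expected:
        exp_bins[-1] += tail_exp
        obs_bins[-1] += tail_obs
    else:
        exp_bins.append(tail_exp)
        obs_bins.append(tail_obs)
    return np.asarray(obs_bins), np.asarray(exp_bins)


def poisson_gof(counts: np.ndarray, min_expected: float = 5.0) -> tuple[float, int, float]:
    """Chi-square goodness of fit of the maximum-likelihood Poisson model.

    The rate is estimated by maximum likelihood (the sample mean), the count
    histogram is compared with ``Poisson(lambda_hat)`` expectations after
    merging tail cells so every bin has expected mass >= ``min_expected``, and
    the statistic is referred to chi-square with ``bins - 2`` degrees of
    freedom (one for the total, one for the estimated rate).  Returns
    ``(statistic, df, p)`` with ``p`` floored at ``2.2e-16``.
    """
    c = np.asarray(counts)
    if c.size < 10:
        raise InputError("need at least 10 sections for the goodness-of-fit test")
    if np.any(c < 0):
        raise InputError("counts must be non-negative")
    lam = float(c.mean())
    if lam == 0:
        raise UndefinedStatisticError("all counts zero: Poisson rate degenerate at 0")
    obs, exp = _merged_poisson_bins(c, lam, min_expected=min_expected)
    if obs.size < 3:
        raise InputError("fewer than 3 merged bins: not enough data for the test")
    # renormalize tiny truncation error so observed and expected totals agree
    exp = exp * (obs.sum() / exp.sum())
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = int(obs.size - 2)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, max(p, P_VALUE_FLOOR)


def dispersion_test(
    counts: np.ndarray, alternative: Literal["greater", "less", "two-sided"] = "greater"
) -> tuple[float, int, float]:
    """Index-of-dispersion test: (n-1) * DI against chi-square with n-1 df.

    Alternative to :func:`poisson_gof`; ``greater`` tests for clustering
    (overdispersion).  Returns ``(statistic, df, p)``, ``p`` floored at 2.2e-16.
    """
    c = np.asarray(counts, dtype=float)
    statistic = (c.size - 1) * dispersion_index(c)
    df = c.size - 1
    upper = stats.chi2.sf(statistic, df)
    lower = stats.chi2.cdf(statistic, df)
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(upper, lower))
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    return float(statistic), int(df), max(float(p), P_VALUE_FLOOR)


def dispersion_report(
    counts: np.ndarray, gof: Literal["chi2_gof", "dispersion"] = "chi2_gof"
) -> DispersionReport:
    """Full dispersion summary (moments, index, goodness of fit) for one count vector."""
    c = np.asarray(counts, dtype=float)
    test = poisson_gof if gof == "chi2_gof" else dispersion_test
    statistic, df, p = test(counts)
    return DispersionReport(
        n=int(c.size),
        mean=float(c.mean()),
        variance=float(c.var(ddof=1)),
        dispersion_index=dispersion_index(counts),
        gof_statistic=statistic,
        gof_df=df,
        gof_p=p,
    )


def cluster_summary(counts: np.ndarray, threshold: int = 32) -> tuple[float, float]:
    """Share of cells in, and share of sections forming, high-count clusters.

    A section is a cluster when its count is strictly greater than
    ``threshold``.  Returns ``(fraction of all cells in cluster sections,
    fraction of sections that are clusters)``.
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total == 0:
        raise UndefinedStatisticError("no cells: cluster fractions undefined")
    in_cluster = c > threshold
    return float(c[in_cluster].sum() / total), float(in_cluster.mean())


def compartment_enrichment(count_fraction: float, area_fraction: float) -> float:
    """Enrichment of a compartment: its share of cells over its share of area."""
    if area_fraction == 0:
        raise UndefinedStatisticError("area fraction 0: enrichment undefined")
    if not (0 < area_fraction <= 1) or not (0 <= count_fraction <= 1):
        raise InputError("fractions must lie in (0, 1]")
    return count_fraction / area_fraction


def image_lrc_threshold(control_cell_intensities: np.ndarray) -> float:
    """Microscopy LRC-calling threshold: 4x the brightest negative-control cell.

    Cells strictly above the returned value are called LRCs in image-derived
    intensity tables.
    """
    c = np.asarray(control_cell_intensities, dtype=float)
    if c.size == 0:
        raise InputError("control intensity list is empty")
    return float(4.0 * c.max())
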