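"""Region-level phasor statistics.

Mirrors the statistical workflow used to compare phasor populations: average
phasor points over >= 15 independently selected image regions per cluster,
the SD of each group of average points, a two-sample t test on the *s*
coordinates of two populations (P < 0.05), a total-least-squares linearity
score for the claim that a cluster sequence is a two-fluorophore ratio, and
the shot-noise law that phasor scatter shrinks as the inverse square root of
the photon count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flim_phasor import PhasorField, PhasorPoint

__all__ = [
    "RegionSet",
    "AveragePoint",
    "PopulationSummary",
    "TTestResult",
    "LinearityReport",
    "region_average_points",
    "population_summary",
    "s_value_ttest",
    "linearity_score",
    "photon_scaling_check",
    "regions_from_labels",
]


@dataclass(frozen=True)
class AveragePoint:
    """Intensity-weighted mean phasor of one selected region."""

    g: float
    s: float
    photons: float
    label: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g) and math.isfinite(self.s)):
            raise ValueError("average point coordinates must be finite")


class RegionSet:
    """Named pixel-index sets over one image.

    Each region is (label, rows, cols) with parallel integer index arrays.
    """

    def __init__(self, regions: Sequence[tuple[str, np.ndarray, np.ndarray]],
                 shape: tuple[int, int]):
        if not regions:
            raise ValueError("need at least one region")
        checked = []
        for label, rows, cols in regions:
            rows = np.asarray(rows, dtype=np.intp)
            cols = np.asarray(cols, dtype=np.intp)
            if rows.size == 0 or rows.shape != cols.shape:
                raise ValueError(f"region {label!r} must be non-empty index arrays")
            if rows.min() < 0 or rows.max() >= shape[0] or cols.min() < 0 or (
                cols.max() >= shape[1]
            ):
                raise ValueError(f"region {label!r} has indices outside the image")
            checked.append((str(label), rows, cols))
        self.regions = checked
        self.shape = shape

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def regions_from_labels(label_img: np.ndarray, prefix: str = "region") -> RegionSet:
    """Build a RegionSet from a label mask (one region per nonzero label)."""
    label_img = np.asarray(label_img)
    regs = []
    for val in np.unique(label_img):
        if val <= 0:
            continue
        rows, cols = np.nonzero(label_img == val)
        regs.append((f"{prefix}{val}", rows, cols))
    return RegionSet(regs, label_img.shape)


def region_average_points(
    field: PhasorField, regions: RegionSet, weighted: bool = True
) -> list[AveragePoint]:
    """Average phasor point of each region over its unmasked pixels.

    Weighted by pixel intensity by default (phasor estimators are
    photon-weighted by construction); pass ``weighted=False`` for a plain
    mean.  A region with no unmasked pixel is an error naming the region.
    """
    if regions.shape != field.shape:
        raise ValueError("regions were defined on a different image shape")
    out = []
    for label, rows, cols in regions:
        ok = field.mask[rows, cols]
        if not ok.any():
            raise ValueError(f"region {label!r} contains no unmasked pixels")
        r, c = rows[ok], cols[ok]
        w = field.intensity[r, c] if weighted else np.ones(r.size)
        wsum = w.sum()
        out.append(
            AveragePoint(
                g=float((field.g[r, c] * w).sum() / wsum),
                s=float((field.s[r, c] * w).sum() / wsum),
                photons=float(field.intensity[r, c].sum()),
                label=label,
            )
        )
    return out


@dataclass
class PopulationSummary:
    """A group of average points with the SD of each coordinate (ddof=1)."""

    points: tuple[AveragePoint, ...]
    sd_g: float
    sd_s: float


def population_summary(points: Sequence[AveragePoint]) -> PopulationSummary:
    if len(points) < 2:
        raise ValueError("a population summary needs at least 2 average points")
    g = np.array([p.g for p in points])
    s = np.array([p.s for p in points])
    return PopulationSummary(
        points=tuple(points),
        sd_g=float(g.std(ddof=1)),
        sd_s=float(s.std(ddof=1)),
    )


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p value must lie in [0, 1]")


def s_value_ttest(
    pop_a: Sequence[AveragePoint],
    pop_b: Sequence[AveragePoint],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample t test on the s coordinates of two average-point groups.

    Welch's unequal-variance variant by default; ``equal_var=True`` selects
    the pooled Student test.  Two constant, identical populations have
    nothing to test: t = 0, p = 1, flagged degenerate.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 average points")
    a = np.array([p.s for p in pop_a])
    b = np.array([p.s for p in pop_b])
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return TTestResult(
            t=0.0,
            df=float(len(a) + len(b) - 2),
            p=1.0,
            significant=False,
            alpha=alpha,
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=p,
        significant=p < alpha,
        alpha=alpha,
    )


@dataclass
class LinearityReport:
    """Total-least-squares line through (g, s) points.

    ``rms_residual`` is the root-mean-square perpendicular distance to the
    line; ``r2`` is the variance fraction captured by the first principal
    direction.  A small residual is the geometric signature of a
    two-fluorophore ratio series.
    """

    direction: tuple[float, float]
    centroid: tuple[float, float]
    rms_residual: float
    r2: float
    degenerate: bool = False


def linearity_score(
    points: Sequence[AveragePoint] | Sequence[PhasorPoint] | np.ndarray,
) -> LinearityReport:
    """Fit a total-least-squares line to phasor points (PCA of the cloud)."""
    arr = np.asarray(
        [(p.g, p.s) if hasattr(p, "g") else tuple(p) for p in points], dtype=float
    )
    if arr.shape[0] < 3:
        raise ValueError("linearity needs at least 3 points")
    centroid = arr.mean(axis=0)
    centered = arr - centroid
    if np.allclose(centered, 0.0):
        return LinearityReport(
            direction=(1.0, 0.0),
            centroid=tuple(centroid),
            rms_residual=0.0,
            r2=1.0,
            degenerate=True,
        )
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    perp = centered @ vt[1]
    var = sv**2
    return LinearityReport(
        direction=(float(direction[0]), float(direction[1])),
        centroid=(float(centroid[0]), float(centroid[1])),
        rms_residual=float(np.sqrt(np.mean(perp**2))),
        r2=float(var[0] / var.sum()),
    )


def photon_scaling_check(
    simulate_pixel: Callable[[int, int], PhasorPoint],
    photon_levels: Sequence[int],
    replicates: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Measure how phasor scatter scales with photon count.

    ``simulate_pixel(n_photons, seed)`` must return one noisy phasor point.
    Returns a table of (photons, sd) - with sd the root of the summed g and s
    variances across replicates - and the fitted log-log slope, which is -1/2
    under pure shot noise.
    """
    if len(photon_levels) < 2:
        raise ValueError("need at least 2 photon levels")
    rows = []
    for i, n in enumerate(photon_levels):
        pts = np.array(
            [
                simulate_pixel(int(n), seed + i * replicates + r)
                for r in range(replicates)
            ]
        )
        sd = math.sqrt(pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
        rows.append({"photons": int(n), "sd": sd})
    table = pd.DataFrame(rows)
    slope = float(
        np.polyfit(np.log(table["photons"]), np.log(table["sd"]), 1)[0]
    )
    return table, slope
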