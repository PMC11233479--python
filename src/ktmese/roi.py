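"""Per-lesion histogram metrics and size from a T2 map and an ROI mask.

The three histogram metrics quantify intratumoural heterogeneity from the
single-slice ROI distribution of pixel T2 values:

* median T2 (ms) — the central tendency compared across subtypes/grades;
* kurtosis — Pearson convention m4/m2² (a Gaussian histogram gives 3);
* skewness — m3/m2^1.5.

Moments are central with denominator n (population convention), matching
common imaging ROI tools.  The largest in-plane diameter is the maximum
Feret diameter: the greatest pixel-centre pairwise distance, computed via
the convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .fitting import T2MapResult

__all__ = [
    "RoiMask",
    "LesionRecord",
    "roi_metrics",
    "largest_diameter",
    "records_to_frame",
]

SUBTYPES = ("RO", "e/oRCC", "chRCC", "pRCC", "ccRCC", "cortex")
MIN_ROI_PIXELS = 10


@dataclass(frozen=True)
class RoiMask:
    """Integer label image aligned to the T2-map grid (single slice)."""

    labels: np.ndarray
    label_names: dict[int, str]
    slice_index: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer array")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        for value, name in self.label_names.items():
            if not np.any(lab == value):
                raise ValueError(f"label {value} ({name}) is empty")

    def pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)


@dataclass
class LesionRecord:
    """One lesion (or cortex reference region) under one protocol."""

    subject_id: str
    lesion_id: str
    subtype: str
    protocol: str
    median_t2_ms: float
    kurtosis: float
    skewness: float
    diameter_mm: float
    n_pixels: int
    who_isup_grade: int | None = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.who_isup_grade is not None:
            if self.subtype != "ccRCC":
                raise ValueError("WHO/ISUP grade applies to ccRCC only")
            if not 1 <= self.who_isup_grade <= 4:
                raise ValueError("grade must be 1..4")
        if self.kurtosis < 1.0:
            raise ValueError("Pearson kurtosis cannot be below 1")


def records_to_frame(records: list[LesionRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "lesion_id": r.lesion_id,
            "subtype": r.subtype,
            "who_isup_grade": r.who_isup_grade,
            "protocol": r.protocol,
            "median_t2_ms": r.median_t2_ms,
            "kurtosis": r.kurtosis,
            "skewness": r.skewness,
            "diameter_mm": r.diameter_mm,
            "n_pixels": r.n_pixels,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def histogram_metrics(values: np.ndarray) -> tuple[float, float, float]:
    """(median, Pearson kurtosis, skewness) of a 1-D sample.

    Biased (denominator-n) central moments; kurtosis is m4/m2² so a Gaussian
    sample sits at 3, skewness is m3/m2^1.5.
    """
    v = np.asarray(values, dtype=float)
    m = v.mean()
    d = v - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero variance: kurtosis/skewness undefined")
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return float(np.median(v)), float(m4 / m2**2), float(m3 / m2**1.5)


def roi_metrics(
    t2map: T2MapResult, mask: RoiMask, label: int
) -> tuple[float, float, float, int]:
    """Median / kurtosis / skewness of valid T2 values under one label.

    Returns ``(median_ms, kurtosis, skewness, n_pixels)``; requires at least
    ``MIN_ROI_PIXELS`` valid pixels.
    """
    sel = (mask.labels == label) & t2map.valid
    vals = t2map.t2_ms[sel]
    if vals.size < MIN_ROI_PIXELS:
        raise ValueError(
            f"only {vals.size} valid pixels under label {label} "
            f"(minimum {MIN_ROI_PIXELS})"
        )
    med, kurt, skew = histogram_metrics(vals)
    return med, kurt, skew, int(vals.size)


def _max_pairwise(points_mm: np.ndarray) -> float:
    if len(points_mm) < 2:
        return 0.0
    return float(pdist(points_mm).max())


def largest_diameter(
    mask: RoiMask, label: int, pixel_spacing_mm: tuple[float, float]
) -> float:
    """Largest in-plane diameter (max-Feret) of a label, in mm.

    Pixel centres are scaled to mm; the maximum pairwise distance is taken
    over convex-hull vertices (which is exact — the diameter of a point set
    is attained on its hull), falling back to all pairs for degenerate sets.
    """
    pts = mask.pixels(label).astype(float)
    if pts.size == 0:
        raise ValueError(f"label {label} is empty")
    pts *= np.asarray(pixel_spacing_mm)[None, :]
    if len(pts) < 4:
        return _max_pairwise(pts)
    try:
        hull = ConvexHull(pts)
        return _max_pairwise(pts[hull.vertices])
    except QhullError:  # collinear masks
        return _max_pairwise(pts)
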