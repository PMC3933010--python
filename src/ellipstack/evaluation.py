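"""Delineation evaluation: Hausdorff distance, Dice overlap, accuracy,
3-mm exceedance counts and cohort median/MAD summaries.

All metrics follow the clinical-evaluation conventions of the delineation
literature:

* per-slice Hausdorff distance between densified contour point sets,
  ``HD(X, Y) = max( max_x min_y d(x,y), max_y min_x d(x,y) )`` in mm, with
  3 mm the usual clinically acceptable threshold;
* Dice volume overlap ``2|X n Y| / (|X| + |Y|)`` on voxelized regions;
* accuracy ``1 - (|FP| + |FN|) / (|TP| + |FN|)`` with the manual contour as
  the reference X.  Note the denominator is |X|, so heavy over-segmentation
  can push accuracy below zero; the value is reported as defined.
* cohort dispersion is the unscaled median absolute deviation
  (median of |x - median|, no 1.4826 consistency factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, UndefinedMetricError

__all__ = [
    "hausdorff_slice",
    "hausdorff_3d",
    "dice",
    "accuracy",
    "count_hd_exceed",
    "summarize_cohort",
    "densify_contour",
    "mad",
]


def densify_contour(points: np.ndarray, n: int = 360) -> np.ndarray:
    """Resample a closed polyline to ``n`` points uniform in arc length."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise InvalidParameterError("need at least 2 points to densify")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InvalidParameterError("contour has zero length")
    u = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(u, s, closed[:, 0])
    y = np.interp(u, s, closed[:, 1])
    return np.column_stack([x, y])


def hausdorff_slice(x_points, y_points) -> float:
    """Symmetric Hausdorff distance (mm) between two point sets."""
    X = np.atleast_2d(np.asarray(x_points, dtype=float))
    Y = np.atleast_2d(np.asarray(y_points, dtype=float))
    if X.size == 0 or Y.size == 0:
        raise InvalidParameterError("point sets must be non-empty")
    d_xy = cKDTree(Y).query(X)[0].max()
    d_yx = cKDTree(X).query(Y)[0].max()
    return float(max(d_xy, d_yx))


def hausdorff_3d(per_slice, agg: str = "mean") -> float:
    """Aggregate per-slice HD values over the slices where both contours
    exist (mean or median)."""
    vals = np.asarray([v for v in per_slice if v is not None and np.isfinite(v)])
    if vals.size == 0:
        raise UndefinedMetricError("no overlapping slices with both contours")
    if agg == "mean":
        return float(np.mean(vals))
    if agg == "median":
        return float(np.median(vals))
    raise InvalidParameterError("agg must be 'mean' or 'median'")


def dice(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Dice similarity coefficient 2|XnY|/(|X|+|Y|) of two binary volumes."""
    X = np.asarray(mask_x, dtype=bool)
    Y = np.asarray(mask_y, dtype=bool)
    if X.shape != Y.shape:
        raise InvalidParameterError("masks must share a grid")
    nx, ny = int(X.sum()), int(Y.sum())
    if nx + ny == 0:
        raise UndefinedMetricError("both masks are empty")
    return 2.0 * int((X & Y).sum()) / (nx + ny)


def accuracy(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """1 - (|FP|+|FN|)/(|TP|+|FN|) with ``mask_x`` the reference.

    The denominator equals |X|; large false-positive volumes make the value
    negative, which is preserved as defined."""
    X = np.asarray(mask_x, dtype=bool)
    Y = np.asarray(mask_y, dtype=bool)
    if X.shape != Y.shape:
        raise InvalidParameterError("masks must share a grid")
    n_ref = int(X.sum())
    if n_ref == 0:
        raise UndefinedMetricError("reference mask is empty")
    fp = int((~X & Y).sum())
    fn = int((X & ~Y).sum())
    return 1.0 - (fp + fn) / n_ref


def count_hd_exceed(per_slice, threshold: float = 3.0) -> tuple:
    """(count of slices with HD > threshold, total slice count)."""
    vals = np.asarray(list(per_slice), dtype=float)
    if vals.size == 0:
        raise InvalidParameterError("need at least one per-slice value")
    return int(np.sum(vals > threshold)), int(vals.size)


def mad(values) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    v = np.asarray(list(values), dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Median and MAD per metric column of a per-case metrics table.

    Returns a two-row frame indexed by 'median' and 'mad', one column per
    numeric column of the input."""
    if len(table) == 0:
        raise InvalidParameterError("need at least one case")
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {c: [float(np.median(num[c])), mad(num[c])] for c in num.columns},
        index=["median", "mad"],
    )
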