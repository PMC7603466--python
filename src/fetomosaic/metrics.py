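"""The three registration error metrics and their summaries.

* **Residual error** — mean squared Euclidean distance between the
  inverse-mapped positions of every integer pixel coordinate of a
  patch under the estimated vs. the ground-truth homography (inverse
  maps, squared norm — implemented literally).
* **4-point RMSE** — root mean square error between ground-truth and
  estimated corner displacements, the quantity the regression network
  optimizes.
* **Photometric error** — mean per-pixel absolute intensity difference
  between the second patch and the first patch reprojected by the
  estimated homography, over pixels that remain inside the source
  (a squared-difference variant is available by flag).

Summaries are reported as box-plot statistics (median, quartiles with
linear interpolation between order statistics, mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .homography import FourPointHomography, normalize_homography

__all__ = [
    "MetricSummary",
    "residual_error",
    "fourpt_rmse",
    "photometric_error",
    "summarize",
]


@dataclass(frozen=True)
class MetricSummary:
    """Box-plot summary of a per-item metric."""

    name: str
    units: str
    median: float
    q1: float
    q3: float
    mean: float
    values: np.ndarray

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "units": self.units,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "mean": self.mean,
            "n": int(len(self.values)),
        }


def _pixel_grid(width: int, height: int):
    xx, yy = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))
    return xx.ravel(), yy.ravel()


def _map_points(h: np.ndarray, xx: np.ndarray, yy: np.ndarray):
    denom = h[2, 0] * xx + h[2, 1] * yy + h[2, 2]
    return (
        (h[0, 0] * xx + h[0, 1] * yy + h[0, 2]) / denom,
        (h[1, 0] * xx + h[1, 1] * yy + h[1, 2]) / denom,
    )


def residual_error(h_est: np.ndarray, h_gt: np.ndarray, patch_w: int, patch_h: int) -> float:
    """Mean squared inverse-map discrepancy over all patch pixels.

    ``mean_i || H_est^-1 x_i - H_gt^-1 x_i ||^2`` over the
    ``patch_w * patch_h`` integer pixel coordinates, in squared pixels.
    """
    if patch_w <= 0 or patch_h <= 0:
        raise ValueError("patch dimensions must be positive")
    inv_est = np.linalg.inv(normalize_homography(h_est))
    inv_gt = np.linalg.inv(normalize_homography(h_gt))
    xx, yy = _pixel_grid(patch_w, patch_h)
    ex, ey = _map_points(inv_est, xx, yy)
    gx, gy = _map_points(inv_gt, xx, yy)
    return float(np.mean((ex - gx) ** 2 + (ey - gy) ** 2))


def fourpt_rmse(fp_gt: FourPointHomography, fp_est: FourPointHomography) -> float:
    """RMSE between ground-truth and estimated corner displacements (px)."""
    d_gt = np.asarray(fp_gt.displacements, dtype=float)
    d_est = np.asarray(fp_est.displacements, dtype=float)
    if d_gt.shape != d_est.shape:
        raise ValueError("corner sets do not match")
    return float(np.sqrt(np.sum((d_gt - d_est) ** 2) / 4.0))


def photometric_error(
    patch_k: np.ndarray,
    patch_k1: np.ndarray,
    h_est: np.ndarray,
    squared: bool = False,
) -> float:
    """Mean per-pixel intensity discrepancy after reprojection.

    ``patch_k`` is warped by the estimated homography into patch k+1's
    coordinates (output pixel x samples ``patch_k`` at ``H x``); the
    mean absolute (or squared) intensity difference is taken over the
    pixels whose source sample stays inside ``patch_k`` — out-of-view
    pixels are excluded from numerator and denominator alike.
    """
    patch_k = np.asarray(patch_k, dtype=float)
    patch_k1 = np.asarray(patch_k1, dtype=float)
    if patch_k.shape != patch_k1.shape:
        raise ValueError("patches must have the same shape")
    h = normalize_homography(h_est)
    ph, pw = patch_k.shape
    xx, yy = _pixel_grid(pw, ph)
    mx, my = _map_points(h, xx, yy)
    valid = (mx >= 0) & (mx <= pw - 1) & (my >= 0) & (my <= ph - 1)
    if not np.any(valid):
        raise ValueError("empty valid region: warp maps the whole patch out of view")
    warped = map_coordinates(patch_k, [my, mx], order=1, mode="constant", cval=0.0)
    diff = (warped - patch_k1.ravel())[valid]
    if squared:
        return float(np.mean(diff**2))
    return float(np.mean(np.abs(diff)))


def summarize(values, name: str = "", units: str = "px") -> MetricSummary:
    """Box-plot summary (median, linear-interpolation quartiles, mean)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot summarize an empty value list")
    if not np.all(np.isfinite(values)):
        raise ValueError("metric values contain non-finite entries")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return MetricSummary(
        name=name,
        units=units,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(values.mean()),
        values=values,
    )
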