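"""Median-consistent pairwise homography estimation.

Single-patch homography estimates on fetoscopic imagery are noisy —
texture paucity, specular highlights and occlusions make some patches
uninformative.  This module implements the outlier-rejection layer: the
pairwise homography between two frames is estimated ``N`` times, each
time from a freshly sampled pair of *co-located* random patches (the
same origin in both frames, as required for the patch-level homography
to equal the frame-level one under rigid motion).  Every estimate is
decomposed into rotation–scale–rotation + translation parameters, the
component-wise median over the ``N`` iterations is taken, and the
median parameters are recomposed into the consistent homography.

With fewer than ``N/2`` corrupted estimates the median is unaffected by
arbitrarily large outliers (the classical 50% breakdown point), which
is what keeps mosaic drift bounded on hard sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .estimators import EstimationFailure, Estimator
from .homography import (
    DecomposedHomography,
    decompose,
    default_corners,
    fourpt_to_matrix,
    recompose,
    wrap_angle,
)

__all__ = [
    "ConsistencyConfig",
    "PairEstimationFailure",
    "sample_patch_locations",
    "consistent_estimate",
    "circular_median",
]


class PairEstimationFailure(RuntimeError):
    """Every single-iteration estimate failed for this frame pair."""


@dataclass(frozen=True)
class ConsistencyConfig:
    """Settings for median-consistent estimation.

    ``n_iterations`` defaults to 99 and must be odd so the median is an
    order statistic (no averaging convention needed); ``patch_size``
    defaults to the 128 px regression-patch size; ``sampling_margin``
    keeps patch origins away from the frame border.
    """

    n_iterations: int = 99
    patch_size: int = 128
    sampling_margin: int = 0
    seed: int = 0
    median_theta_only: bool = False

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_iterations % 2 == 0:
            raise ValueError("n_iterations must be a positive odd number")
        if self.patch_size < 8:
            raise ValueError("patch_size too small")
        if self.sampling_margin < 0:
            raise ValueError("sampling_margin must be >= 0")


def sample_patch_locations(
    frame_size,
    cfg: ConsistencyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_iterations`` patch origins uniformly over the valid region.

    ``frame_size`` is (height, width) or a single int.  Origins are
    integer (x, y) pairs in ``[margin, size - patch - margin]``
    inclusive; the same origin is used in both frames of a pair.
    """
    if np.isscalar(frame_size):
        fh = fw = int(frame_size)
    else:
        fh, fw = int(frame_size[0]), int(frame_size[1])
    lo = cfg.sampling_margin
    hi_x = fw - cfg.patch_size - cfg.sampling_margin
    hi_y = fh - cfg.patch_size - cfg.sampling_margin
    if hi_x < lo or hi_y < lo:
        raise ValueError(
            f"frame {fh}x{fw} too small for patch {cfg.patch_size} "
            f"with margin {cfg.sampling_margin}"
        )
    xs = rng.integers(lo, hi_x + 1, size=cfg.n_iterations)
    ys = rng.integers(lo, hi_y + 1, size=cfg.n_iterations)
    return np.stack([xs, ys], axis=1)


def circular_median(angles: np.ndarray) -> float:
    """Median of angles on the circle, robust to the ±pi seam.

    The sample is rebased around its circular mean before taking the
    ordinary median, then mapped back to (-pi, pi], so samples
    straddling the branch cut (e.g. 179.5° ± 1°) keep their true
    central value.
    """
    angles = np.asarray(angles, dtype=float)
    ref = np.arctan2(np.sin(angles).mean(), np.cos(angles).mean())
    rebased = np.array([wrap_angle(a - ref) for a in angles])
    return wrap_angle(float(np.median(rebased)) + ref)


def consistent_estimate(
    frame_k: np.ndarray,
    frame_k1: np.ndarray,
    estimator: Estimator,
    cfg: Optional[ConsistencyConfig] = None,
    pair_index: int = 0,
    diagnostics: Optional[list] = None,
) -> np.ndarray:
    """Estimate the homography mapping frame k+1 into frame k, robustly.

    Runs the backend on ``cfg.n_iterations`` co-located random patch
    pairs, decomposes every estimate, takes parameter-wise medians and
    recomposes.  Individual estimation failures are dropped (with a
    warning when fewer than half the iterations survive); if all fail a
    :class:`PairEstimationFailure` is raised for the caller to handle
    (the sequence pipeline substitutes the identity and logs).

    Parameters
    ----------
    diagnostics : list, optional
        Receives one 6-tuple (theta, gamma, s_g, s_h, t_x, t_y) per
        surviving iteration, for inspection/CSV dumping.
    """
    cfg = cfg or ConsistencyConfig()
    frame_k = np.asarray(frame_k, dtype=float)
    frame_k1 = np.asarray(frame_k1, dtype=float)
    if frame_k.shape != frame_k1.shape:
        raise ValueError("frames must have the same shape")
    rng = np.random.default_rng([cfg.seed, pair_index])
    origins = sample_patch_locations(frame_k.shape, cfg, rng)
    estimator.begin_pair(pair_index)
    base_corners = default_corners(cfg.patch_size, cfg.patch_size)
    params = []
    n_failed = 0
    for ox, oy in origins:
        pa = frame_k[oy : oy + cfg.patch_size, ox : ox + cfg.patch_size]
        pb = frame_k1[oy : oy + cfg.patch_size, ox : ox + cfg.patch_size]
        corners = base_corners + [ox, oy]
        try:
            fp = estimator.estimate(pa, pb, corners=corners)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # single estimates may be non-affine
                d = decompose(fourpt_to_matrix(fp))
        except (EstimationFailure, ValueError):
            n_failed += 1
            continue
        params.append(d.as_array())
    if not params:
        raise PairEstimationFailure(
            f"all {cfg.n_iterations} estimations failed for pair {pair_index}"
        )
    if n_failed > 0 and len(params) < cfg.n_iterations / 2:
        warnings.warn(
            f"pair {pair_index}: only {len(params)}/{cfg.n_iterations} "
            "iterations produced estimates; median may be unreliable",
            stacklevel=2,
        )
    arr = np.array(params)  # (n, 6): theta, gamma, s_g, s_h, t_x, t_y
    if diagnostics is not None:
        diagnostics.extend(map(tuple, arr))
    if cfg.median_theta_only:
        # literal reading: pick the iteration whose theta attains the median
        order = np.argsort(arr[:, 0], kind="stable")
        pick = order[(len(order) - 1) // 2]
        med = arr[pick]
    else:
        # The split of the total rotation between theta and gamma is
        # ill-conditioned when the two scales are nearly equal (the
        # regime of near-rigid motion), so raw per-component medians of
        # theta and gamma do not average noise down.  Median the stable
        # quantities instead: the total (polar) rotation phi = theta +
        # gamma and the anisotropy orientation gamma, then recover
        # theta = med(phi) - med(gamma).  For well-separated scales, or
        # a majority of identical estimates, this coincides with the
        # plain component-wise median.
        phi = np.array([wrap_angle(t + g) for t, g in zip(arr[:, 0], arr[:, 1])])
        med_phi = circular_median(phi)
        med_gamma = circular_median(arr[:, 1])
        med = np.array(
            [
                wrap_angle(med_phi - med_gamma),
                med_gamma,
                np.median(arr[:, 2]),
                np.median(arr[:, 3]),
                np.median(arr[:, 4]),
                np.median(arr[:, 5]),
            ]
        )
    d = DecomposedHomography(
        theta=wrap_angle(med[0]),
        gamma=wrap_angle(med[1]),
        s_g=float(med[2]),
        s_h=float(med[3]),
        t_x=float(med[4]),
        t_y=float(med[5]),
    )
    return recompose(d)
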