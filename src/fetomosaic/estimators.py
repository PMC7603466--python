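"""Pairwise homography estimation backends.

All backends share one contract: ``estimate(patch_a, patch_b, corners)``
returns the :class:`~fetomosaic.homography.FourPointHomography` whose
matrix maps patch-B coordinates onto patch-A coordinates (for video,
frame ``k+1`` into frame ``k``).  Displacements are measured at the
patch corners; when ``corners`` are given in frame coordinates the same
displacements are attached to them, which — for co-located patches —
makes the DLT of the result the frame-level homography directly, with
no extra shift correction.

Backends:

* :class:`FeatureEstimator` — the classical baseline: local features
  (SIFT by default; ORB selectable), brute-force ratio-test matching,
  RANSAC homography fit.
* :class:`RegressionEstimator` — the trained convolutional 4-point
  regressor (see :mod:`fetomosaic.net`), with :func:`train_regression`
  supporting both the controlled (rotation+translation) and the random
  corner-perturbation training regimes.
* :class:`OracleEstimator` — returns ground truth, optionally corrupted
  with seeded noise and outliers; the testing backend.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import ORB, SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, resize

from .homography import (
    FourPointHomography,
    apply_homography,
    default_corners,
    normalize_homography,
    rigid_matrix,
    translation_matrix,
)
from .net import HomographyNet, RegressionNetSpec
from .synth import generate_controlled_pair, generate_perturbed_pair, generate_texture

__all__ = [
    "EstimationFailure",
    "Estimator",
    "FeatureEstimator",
    "OracleEstimator",
    "RegressionEstimator",
    "train_regression",
]


class EstimationFailure(RuntimeError):
    """The backend could not produce a usable homography for this pair."""


class Estimator:
    """Base estimation contract."""

    name: str = "base"
    is_deterministic: bool = True

    def begin_pair(self, pair_index: int) -> None:
        """Hook called by sequence drivers before each frame pair."""

    def estimate(
        self,
        patch_a: np.ndarray,
        patch_b: np.ndarray,
        corners: Optional[np.ndarray] = None,
    ) -> FourPointHomography:
        raise NotImplementedError

    def _resolve_corners(self, patch_a: np.ndarray, corners) -> np.ndarray:
        if corners is None:
            h, w = patch_a.shape[:2]
            return default_corners(w, h)
        return np.asarray(corners, dtype=float)


class FeatureEstimator(Estimator):
    """Feature-matching baseline: detect, match exhaustively, fit robustly.

    Local features are detected in both patches, matched by brute-force
    descriptor comparison with a ratio test and cross-check, and a
    projective model is fitted to the matches by RANSAC (3 px
    reprojection threshold, 2000 trials, fixed seed).  Raises
    :class:`EstimationFailure` when fewer than 4 usable matches survive.
    """

    is_deterministic = True

    def __init__(
        self,
        detector: str = "sift",
        max_ratio: float = 0.8,
        residual_threshold: float = 3.0,
        max_trials: int = 2000,
        seed: int = 0,
        min_inliers: int = 4,
        c_dog: float = 0.004,
    ):
        if detector not in ("sift", "orb"):
            raise ValueError("detector must be 'sift' or 'orb'")
        self.detector = detector
        # DoG contrast threshold lowered from skimage's natural-image
        # default: endoscopic/placental imagery is low-contrast
        self.c_dog = c_dog
        self.max_ratio = max_ratio
        self.residual_threshold = residual_threshold
        self.max_trials = max_trials
        self.seed = seed
        self.min_inliers = min_inliers
        self.name = f"feat-{detector}"

    def _detect(self, patch: np.ndarray):
        if self.detector == "sift":
            det = SIFT(c_dog=self.c_dog)
        else:
            det = ORB(n_keypoints=500)
        try:
            det.detect_and_extract(patch)
        except RuntimeError as e:  # skimage raises when nothing is found
            raise EstimationFailure(f"no features detected: {e}") from e
        if det.keypoints.shape[0] < 4:
            raise EstimationFailure("fewer than 4 keypoints detected")
        return det.keypoints[:, ::-1].astype(float), det.descriptors  # (row,col) -> (x,y)

    def estimate(self, patch_a, patch_b, corners=None) -> FourPointHomography:
        patch_a = np.asarray(patch_a, dtype=float)
        patch_b = np.asarray(patch_b, dtype=float)
        if patch_a.shape != patch_b.shape:
            raise ValueError("patches must have the same shape")
        if patch_a.std() < 1e-8 or patch_b.std() < 1e-8:
            raise EstimationFailure("constant-intensity patch")
        kp_a, desc_a = self._detect(patch_a)
        kp_b, desc_b = self._detect(patch_b)
        matches = match_descriptors(
            desc_b, desc_a, cross_check=True, max_ratio=self.max_ratio
        )
        if matches.shape[0] < 4:
            raise EstimationFailure(f"only {matches.shape[0]} descriptor matches")
        src = kp_b[matches[:, 0]]  # patch-B points ...
        dst = kp_a[matches[:, 1]]  # ... map onto patch-A points
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, inliers = ransac(
                (src, dst),
                ProjectiveTransform,
                min_samples=4,
                residual_threshold=self.residual_threshold,
                max_trials=self.max_trials,
                rng=self.seed,
            )
        if model is None or inliers is None or inliers.sum() < self.min_inliers:
            raise EstimationFailure("RANSAC failed to find a consistent model")
        h = model.params
        if not np.all(np.isfinite(h)) or abs(np.linalg.det(h)) < 1e-12:
            raise EstimationFailure("degenerate homography from RANSAC")
        h = normalize_homography(h)
        ph, pw = patch_a.shape
        local = default_corners(pw, ph)
        disp = apply_homography(h, local) - local
        out_corners = self._resolve_corners(patch_a, corners)
        return FourPointHomography(corners=out_corners, displacements=disp)


class OracleEstimator(Estimator):
    """Ground-truth backend with configurable corruption (testing only).

    Displacements are read off the true frame-level homography at the
    requested corners, then optionally perturbed with zero-mean Gaussian
    noise (``noise_sigma`` pixels per displacement component) and/or
    replaced by outliers: estimates computed from the ground truth
    composed with a large rigid offset (``outlier_rotation_deg``,
    ``outlier_translation``).  Outliers are injected either with i.i.d.
    probability ``outlier_prob`` or as exactly ``n_outliers`` of each
    block of ``outliers_of`` calls per pair (seeded positions).
    """

    def __init__(
        self,
        gts: Sequence[np.ndarray] | np.ndarray | Callable[[int], np.ndarray],
        noise_sigma: float = 0.0,
        outlier_prob: float = 0.0,
        n_outliers: Optional[int] = None,
        outliers_of: Optional[int] = None,
        outlier_rotation_deg: float = 20.0,
        outlier_translation: Tuple[float, float] = (50.0, 0.0),
        seed: int = 0,
    ):
        if callable(gts):
            self._gt_of = gts
        elif isinstance(gts, np.ndarray) and gts.shape == (3, 3):
            self._gt_of = lambda k, _h=normalize_homography(gts): _h
        else:
            mats = [normalize_homography(g) for g in gts]
            self._gt_of = lambda k, _m=mats: _m[k]
        self.noise_sigma = noise_sigma
        self.outlier_prob = outlier_prob
        self.n_outliers = n_outliers
        self.outliers_of = outliers_of
        if (n_outliers is None) != (outliers_of is None):
            raise ValueError("n_outliers and outliers_of must be given together")
        self.outlier_rotation_deg = outlier_rotation_deg
        self.outlier_translation = outlier_translation
        self.seed = seed
        self.name = "oracle"
        self.is_deterministic = noise_sigma == 0 and outlier_prob == 0 and n_outliers is None
        self.begin_pair(0)

    def begin_pair(self, pair_index: int) -> None:
        self._pair = pair_index
        self._call = 0
        self._rng = np.random.default_rng([self.seed, pair_index])
        if self.n_outliers is not None:
            flags = np.zeros(self.outliers_of, dtype=bool)
            flags[: self.n_outliers] = True
            self._rng.shuffle(flags)
            self._flags = flags
        else:
            self._flags = None

    def _is_outlier(self) -> bool:
        if self._flags is not None:
            if self._call < len(self._flags):
                return bool(self._flags[self._call])
            return bool(self._rng.uniform() < self.n_outliers / self.outliers_of)
        if self.outlier_prob > 0:
            return bool(self._rng.uniform() < self.outlier_prob)
        return False

    def estimate(self, patch_a, patch_b, corners=None) -> FourPointHomography:
        gt = self._gt_of(self._pair)
        if gt is None:
            raise EstimationFailure(f"no ground truth available for pair {self._pair}")
        out_corners = self._resolve_corners(np.asarray(patch_a), corners)
        h = gt
        if self._is_outlier():
            offset = translation_matrix(*self.outlier_translation) @ rigid_matrix(
                self.outlier_rotation_deg, 0.0, 0.0, degrees=True
            )
            h = offset @ gt
        disp = apply_homography(h, out_corners) - out_corners
        if self.noise_sigma > 0:
            disp = disp + self._rng.normal(0.0, self.noise_sigma, size=disp.shape)
        self._call += 1
        return FourPointHomography(corners=out_corners, displacements=disp)


def _stack_patches(patch_a: np.ndarray, patch_b: np.ndarray, size: int) -> np.ndarray:
    """Downsample two patches to (2, size, size) in [-1, 1]."""
    out = np.empty((2, size, size))
    for i, p in enumerate((patch_a, patch_b)):
        p = np.asarray(p, dtype=float)
        if p.shape != (size, size):
            s = p.shape[0]
            if s % size == 0:  # exact block mean, cheap and deterministic
                f = s // size
                p = p.reshape(size, f, size, f).mean(axis=(1, 3))
            else:
                p = resize(p, (size, size), order=1, anti_aliasing=True)
        out[i] = p * 2.0 - 1.0
    return out


class RegressionEstimator(Estimator):
    """4-point homography regression backend wrapping a trained network."""

    is_deterministic = True

    def __init__(self, net: HomographyNet, name: str = "dih"):
        self.net = net
        self.name = name

    def estimate(self, patch_a, patch_b, corners=None) -> FourPointHomography:
        patch_a = np.asarray(patch_a, dtype=float)
        patch_b = np.asarray(patch_b, dtype=float)
        if patch_a.shape != patch_b.shape:
            raise ValueError("patches must have the same shape")
        x = _stack_patches(patch_a, patch_b, self.net.spec.input_size)[None]
        disp = self.net.predict_displacements(x)[0].reshape(4, 2)
        if not np.all(np.isfinite(disp)):
            raise EstimationFailure("network produced non-finite displacements")
        out_corners = self._resolve_corners(patch_a, corners)
        return FourPointHomography(corners=out_corners, displacements=disp)


def train_regression(
    spec: Optional[RegressionNetSpec] = None,
    images: Optional[Sequence[np.ndarray]] = None,
    steps: int = 2000,
    seed: int = 0,
    controlled: bool = True,
    patch_size: int = 128,
    max_perturb: float = 16.0,
    log: Optional[list] = None,
) -> RegressionEstimator:
    """Train the regression network on run-time-minted patch pairs.

    Each optimization step draws a fresh batch of patch pairs from the
    training images — the controlled rigid model when ``controlled`` is
    true, otherwise independent corner perturbation up to
    ``max_perturb`` px — and minimizes the Euclidean loss on the
    normalized displacements.  Fully deterministic for a given seed.

    Parameters
    ----------
    images : sequence of 2D arrays, optional
        Grayscale training images (>= 256x256, [0, 1]).  When omitted,
        a small bank of synthetic placental textures is generated.
    steps : int
        Number of batches; ``steps=0`` returns the untrained network.
    log : list, optional
        Receives ``(step, loss)`` tuples.
    """
    spec = spec or RegressionNetSpec.desk()
    if steps < 0:
        raise ValueError("steps must be >= 0")
    rng = np.random.default_rng([seed, 17])
    if images is None:
        images = [
            generate_texture(256, 256, rng=np.random.default_rng([seed, 101 + i]))
            for i in range(8)
        ]
    elif len(images) == 0:
        raise ValueError("need at least one training image")
    net = HomographyNet(spec, seed=seed)
    for step in range(steps):
        xb = np.empty((spec.batch_size, 2, spec.input_size, spec.input_size))
        tb = np.empty((spec.batch_size, 8))
        for j in range(spec.batch_size):
            img = images[rng.integers(len(images))]
            if controlled:
                pair = generate_controlled_pair(img, rng=rng, patch_size=patch_size)
            else:
                pair = generate_perturbed_pair(
                    img, max_perturb=max_perturb, rng=rng, patch_size=patch_size
                )
            xb[j] = _stack_patches(pair.patch_a, pair.patch_b, spec.input_size)
            tb[j] = pair.gt.to_flat() / spec.disp_scale
        loss = net.train_step(xb, tb)
        if log is not None:
            log.append((step, loss))
    regime = "controlled" if controlled else "perturbed"
    return RegressionEstimator(net, name=f"dih-{regime}")
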