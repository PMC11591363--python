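"""Planar projective (homography) correction of camera coordinates.

The tunnel-walk recordings are a single oblique view of a planar walking
surface, so the mapping from image pixels to arena coordinates is a 3x3
homography determined exactly by four point correspondences.  Estimation
uses the direct linear transform on the four calibration points, with
Hartley-style normalization (translate to the centroid, scale to RMS
radius sqrt(2)) of both point sets for numerical conditioning.

The destination frame is arena centimeters with y pointing up, so the same
matrix also performs the video-to-physical axis flip.  A homography cannot
represent radial lens distortion; this module implements the pure
projective correction only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ArityError,
    DegenerateConfigurationError,
    NumericError,
    ProjectiveInfinityError,
)
from .io_tracks import CalibrationSet

_DET_TOL = 1e-12
_RESIDUAL_TOL = 1e-8
_W_TOL = 1e-12


@dataclass
class Homography:
    """3x3 projective transform, normalized so H[2, 2] == 1."""

    H: np.ndarray
    src_units: str = "px"
    dst_units: str = "cm"

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=np.float64)
        if H.shape != (3, 3):
            raise NumericError(f"homography must be 3x3, got {H.shape}")
        if abs(H[2, 2]) < _W_TOL:
            raise NumericError("cannot normalize homography: H[2, 2] ~ 0")
        H = H / H[2, 2]
        if abs(np.linalg.det(H)) <= _DET_TOL:
            raise NumericError("homography is singular after normalization")
        self.H = H

    @classmethod
    def identity(cls, src_units: str = "px", dst_units: str = "cm") -> "Homography":
        return cls(np.eye(3), src_units=src_units, dst_units=dst_units)


def _collinearity_check(pts: np.ndarray, label: str) -> None:
    """Reject configurations where any 3 of the 4 points are collinear.

    The tolerance is relative to the bounding-box area so the check is
    invariant to the coordinate scale (pixels vs centimeters).
    """
    span = pts.max(axis=0) - pts.min(axis=0)
    bbox_area = float(span[0] * span[1])
    if bbox_area <= 0.0:
        raise DegenerateConfigurationError(f"{label} points are collinear or coincident")
    idx = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for i, j, k in idx:
        v1 = pts[j] - pts[i]
        v2 = pts[k] - pts[i]
        area = 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0])
        if area <= 1e-9 * bbox_area:
            raise DegenerateConfigurationError(
                f"{label} points {i}, {j}, {k} are collinear (triangle area "
                f"{area:.3e} vs bbox {bbox_area:.3e})"
            )


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform taking ``pts`` to centroid 0, RMS radius sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if rms < 1e-15:
        raise DegenerateConfigurationError("coincident calibration points")
    s = np.sqrt(2.0) / rms
    T = np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )
    return T


def estimate_homography(
    cal: CalibrationSet, src_units: str = "px", dst_units: str = "cm"
) -> Homography:
    """Exact 4-point DLT estimate of the pixel-to-arena homography.

    Builds the 8x9 homogeneous system in normalized coordinates, takes the
    null-space via SVD, and denormalizes.  The result reproduces every
    calibration correspondence to a relative 1e-8.
    """
    src = np.asarray(cal.src, dtype=np.float64)
    dst = np.asarray(cal.dst, dtype=np.float64)
    if src.shape != (4, 2) or dst.shape != (4, 2):
        raise ArityError(
            f"exactly 4 correspondences required, got src {src.shape}, dst {dst.shape}"
        )
    _collinearity_check(src, "source")
    _collinearity_check(dst, "destination")

    Ts = _hartley_normalization(src)
    Td = _hartley_normalization(dst)
    src_n = (Ts @ np.column_stack([src, np.ones(4)]).T).T[:, :2]
    dst_n = (Td @ np.column_stack([dst, np.ones(4)]).T).T[:, :2]

    A = np.zeros((8, 9))
    for r, ((x, y), (u, v)) in enumerate(zip(src_n, dst_n)):
        A[2 * r] = [-x, -y, -1.0, 0.0, 0.0, 0.0, u * x, u * y, u]
        A[2 * r + 1] = [0.0, 0.0, 0.0, -x, -y, -1.0, v * x, v * y, v]
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    hom = Homography(H, src_units=src_units, dst_units=dst_units)

    mapped = apply_homography(hom, src)
    scale = max(np.abs(dst).max(), 1.0)
    resid = np.linalg.norm(mapped - dst, axis=1).max()
    if resid > _RESIDUAL_TOL * scale:
        raise NumericError(
            f"homography residual {resid:.3e} exceeds {_RESIDUAL_TOL:.0e} x scale"
        )
    return hom


def apply_homography(H: Homography, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) points projectively: (x', y') = (H.(x, y, 1)) dehomogenized."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ H.H.T
    w = out[:, 2]
    bad = np.abs(w) <= _W_TOL
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ProjectiveInfinityError(
            f"point {tuple(pts[i])} maps to the line at infinity (w = {w[i]:.3e})"
        )
    return out[:, :2] / w[:, None]


def invert_homography(H: Homography) -> Homography:
    """Inverse transform (units swapped); H . inv(H) = I to 1e-10."""
    try:
        Hinv = np.linalg.inv(H.H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by det check
        raise NumericError(f"homography not invertible: {exc}") from exc
    return Homography(Hinv, src_units=H.dst_units, dst_units=H.src_units)
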