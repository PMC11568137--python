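"""2-D similarity transforms and least-squares estimation from point pairs.

Estimation is the closed-form orthogonal-Procrustes-with-scale (Umeyama)
solution minimizing sum ||s R p + t - q||^2, exact on noiseless consistent
pairs. The same math backs both the automatic path and the manual
junction-pair entry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class EstimationError(ValueError):
    """Raised when a transform cannot be estimated from the given pairs."""


@dataclass(frozen=True)
class PointSet:
    """Finite 2-D points tagged with the frame they live in."""

    xy: np.ndarray          # (n, 2)
    frame: str              # e.g. "device-px" | "oct-enface-um"

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(xy)):
            raise ValueError("points must be finite")
        if not self.frame:
            raise ValueError("frame tag required")
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.xy.shape[0]


@dataclass(frozen=True)
class SimilarityTransform:
    scale: float
    rotation_rad: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        """2x3 matrix [sR | t]."""
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        return np.array([
            [self.scale * c, -self.scale * s, self.translation[0]],
            [self.scale * s, self.scale * c, self.translation[1]],
        ])

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        out = pts @ m[:, :2].T + m[:, 2]
        return out

    def inverse(self) -> "SimilarityTransform":
        s = 1.0 / self.scale
        r = -self.rotation_rad
        c, sn = math.cos(r), math.sin(r)
        tx, ty = self.translation
        itx = -s * (c * tx - sn * ty)
        ity = -s * (sn * tx + c * ty)
        return SimilarityTransform(s, r, (itx, ity))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self o other: apply ``other`` first."""
        s = self.scale * other.scale
        r = _wrap_angle(self.rotation_rad + other.rotation_rad)
        t = self.apply(np.array(other.translation))[0]
        return SimilarityTransform(s, r, (float(t[0]), float(t[1])))


def _wrap_angle(a: float) -> float:
    return math.atan2(math.sin(a), math.cos(a))


def estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity mapping ``src`` onto ``dst``.

    Requires at least two distinct source points; degenerate (coincident)
    configurations raise :class:`EstimationError`.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise EstimationError("src and dst must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 2 or np.unique(src, axis=0).shape[0] < 2:
        raise EstimationError("need >= 2 distinct point pairs")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_s = float(np.sum(sc ** 2)) / n
    if var_s <= 0:
        raise EstimationError("source points are coincident")
    cov = dc.T @ sc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S)) / var_s
    if scale <= 0 or not np.isfinite(scale):
        raise EstimationError("degenerate configuration (non-positive scale)")
    t = mu_d - scale * (R @ mu_s)
    rot = math.atan2(R[1, 0], R[0, 0])
    return SimilarityTransform(scale, rot, (float(t[0]), float(t[1])))


def manual_pairs_to_transform(pairs) -> SimilarityTransform:
    """Human-correction entry point: estimate from explicit junction pairs.

    ``pairs`` is an iterable of ``((sx, sy), (dx, dy))`` tuples; the math is
    identical to :func:`estimate_similarity`.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise EstimationError("need >= 2 pairs")
    src = np.array([p[0] for p in pairs], dtype=float)
    dst = np.array([p[1] for p in pairs], dtype=float)
    return estimate_similarity(src, dst)


def rmse_um(transform: SimilarityTransform, src: np.ndarray,
            dst: np.ndarray) -> float:
    """Root-mean-square residual of ``transform`` over matched pairs."""
    res = transform.apply(src) - np.atleast_2d(dst)
    return float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
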