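"""End-to-end acquisition registration and B-scan lookup.

Composes vessel segmentation, junction detection, robust matching and
least-squares transform estimation to map a device fundus raster into the
OCT en-face frame, with quality gates for the human-review path.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from ..geometry import OCTGeometry
from .junctions import detect_junctions
from .matching import MatchConfig, MatchFailure, match_junctions
from .transform import PointSet, SimilarityTransform
from .vessels import VesselSegConfig, segment_vessels


@dataclass(frozen=True)
class RegistrationConfig:
    vessels: VesselSegConfig = VesselSegConfig()
    # bounds on the device-pixel -> um scale; the nominal device pixel
    # pitch is known a priori, so a tight band is justified and sharply
    # reduces the RANSAC search space
    match: MatchConfig = MatchConfig(scale_bounds=(7.0, 13.0))
    merge_radius_px: float = 5.0
    max_rmse_um: float = 35.0
    min_inliers: int = 4


@dataclass
class RegistrationResult:
    """Estimated device-px -> en-face-um transform plus quality surface."""

    transform: SimilarityTransform
    matched_pairs: list[tuple[int, int]]
    rmse_um: float
    n_inliers: int
    ok: bool

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.matrix.tolist(),
            "scale": self.transform.scale,
            "rotation_rad": self.transform.rotation_rad,
            "translation": list(self.transform.translation),
            "rmse_um": self.rmse_um,
            "n_inliers": self.n_inliers,
            "matched_pairs": [list(p) for p in self.matched_pairs],
            "ok": self.ok,
        }


def register_acquisition(device_raster: np.ndarray, nir_raster: np.ndarray,
                         nir_um_per_px: float, seed: int = 0,
                         config: RegistrationConfig | None = None
                         ) -> RegistrationResult:
    """Register a device fundus raster to the OCT-NIR raster.

    The returned transform maps device pixels directly into en-face um
    (the NIR frame is converted by its pixel pitch). Results with
    RMSE > 35 um or fewer than 4 inliers are flagged ``ok=False`` for
    manual correction; a failed match propagates as
    :class:`~mpoct.register.matching.MatchFailure`.
    """
    if config is None:
        config = RegistrationConfig()
    dev_mask = segment_vessels(device_raster, config.vessels)
    nir_mask = segment_vessels(nir_raster, config.vessels)
    dev_j = detect_junctions(dev_mask, frame="device-px",
                             merge_radius_px=config.merge_radius_px)
    nir_j = detect_junctions(nir_mask, frame="oct-enface-px",
                             merge_radius_px=config.merge_radius_px)
    nir_um = PointSet(nir_j.xy * nir_um_per_px, frame="oct-enface-um")
    match = match_junctions(dev_j, nir_um, seed=seed, config=config.match)
    ok = (match.rmse <= config.max_rmse_um
          and len(match.pairs) >= config.min_inliers)
    return RegistrationResult(transform=match.transform,
                              matched_pairs=match.pairs,
                              rmse_um=match.rmse,
                              n_inliers=len(match.pairs), ok=ok)


OUT_OF_AREA = None


def enface_to_bscan(point_xy_um: tuple[float, float],
                    geometry: OCTGeometry):
    """Locate an en-face point on the cube: (bscan, ascan) indices.

    Nearest-index rounding with the round-half-down tie rule (a point
    exactly between two B-scans maps to the lower index). Points outside
    the scanned field return ``None`` (out-of-area marker).
    """
    x, y = point_xy_um
    if not geometry.contains(x, y):
        return OUT_OF_AREA
    a = math.ceil(x / geometry.ascan_spacing_um - 0.5)
    b = math.ceil(y / geometry.bscan_spacing_um - 0.5)
    a = min(max(a, 0), geometry.n_ascans - 1)
    b = min(max(b, 0), geometry.n_bscans - 1)
    return (b, a)
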