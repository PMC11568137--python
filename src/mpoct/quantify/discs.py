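"""Per-stimulus disc extraction and biomarker aggregation.

Biomarkers are quantified over all en-face pixels whose centres fall within
a fixed radius (default 70 um) of the stimulus centre, honouring the
anisotropic A-scan/B-scan spacing of the cube.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..geometry import OCTGeometry

#: conversion between cubic micrometres and nanolitres
UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class QuantConfig:
    radius_um: float = 70.0
    hrf_threshold_nl: float = 0.06
    maia_floor_adjust: bool = True
    #: apply the component-volume threshold per disc instead of globally
    hrf_disc_level_threshold: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.hrf_threshold_nl < 0:
            raise ValueError("hrf_threshold_nl must be >= 0")


def disc_pixels(center_xy_um: tuple[float, float], geometry: OCTGeometry,
                radius_um: float = 70.0) -> np.ndarray:
    """Pixels whose centres lie within ``radius_um`` of the stimulus centre.

    Returns an ``(n, 2)`` integer array of ``(bscan, ascan)`` indices;
    empty when the disc misses the scanned field entirely. Membership is
    pixel-centre-in-circle (inclusive) with no partial-area weighting.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    cx, cy = center_xy_um
    dx = geometry.ascan_spacing_um
    dy = geometry.bscan_spacing_um
    a_lo = max(0, math.ceil((cx - radius_um) / dx))
    a_hi = min(geometry.n_ascans - 1, math.floor((cx + radius_um) / dx))
    b_lo = max(0, math.ceil((cy - radius_um) / dy))
    b_hi = min(geometry.n_bscans - 1, math.floor((cy + radius_um) / dy))
    if a_lo > a_hi or b_lo > b_hi:
        return np.empty((0, 2), dtype=np.intp)
    aa = np.arange(a_lo, a_hi + 1)
    bb = np.arange(b_lo, b_hi + 1)
    A, B = np.meshgrid(aa, bb)
    inside = (A * dx - cx) ** 2 + (B * dy - cy) ** 2 <= radius_um ** 2
    return np.column_stack([B[inside], A[inside]]).astype(np.intp)


def mean_thickness(raster: np.ndarray, disc: np.ndarray) -> float:
    """Arithmetic mean of a thickness raster over disc pixels (um).

    Empty discs yield NaN (missing value).
    """
    if disc.shape[0] == 0:
        return float("nan")
    return float(np.mean(raster[disc[:, 0], disc[:, 1]]))


def volume_in_disc(height_raster: np.ndarray, disc: np.ndarray,
                   geometry: OCTGeometry) -> float:
    """Integrate a height map (um) over the disc, in nanolitres."""
    if disc.shape[0] == 0:
        return float("nan")
    total_um3 = float(np.sum(height_raster[disc[:, 0], disc[:, 1]])) * geometry.pixel_area_um2
    return total_um3 / UM3_PER_NL


def hrf_volume_in_disc(hrf_components, disc: np.ndarray,
                       config: QuantConfig | None = None) -> float:
    """In-disc hyperreflective-foci volume after component-level filtering.

    Components whose *total* volume does not exceed the threshold (default
    0.06 nl) are discarded; surviving components contribute the volume of
    their voxels that fall inside the disc. With
    ``hrf_disc_level_threshold`` the threshold is instead applied to the
    in-disc contribution of each component.
    """
    if config is None:
        config = QuantConfig()
    if disc.shape[0] == 0:
        return float("nan")
    disc_set = {(int(b), int(a)) for b, a in disc}
    total = 0.0
    for comp in hrf_components:
        in_disc = sum(
            float(v) for (b, a), v in zip(comp.pixels, comp.voxel_volumes_nl)
            if (int(b), int(a)) in disc_set
        )
        if config.hrf_disc_level_threshold:
            if in_disc > config.hrf_threshold_nl:
                total += in_disc
        else:
            if comp.total_volume_nl > config.hrf_threshold_nl:
                total += in_disc
    return total


def eccentricity_deg(point_xy_um: tuple[float, float],
                     fovea_xy_um: tuple[float, float],
                     geometry: OCTGeometry) -> float:
    """Radial eccentricity of an en-face point from the fovea, in degrees."""
    d = math.hypot(point_xy_um[0] - fovea_xy_um[0], point_xy_um[1] - fovea_xy_um[1])
    return d / geometry.um_per_deg


#: device measurement ranges: raw export range and adjusted (analysis) range
DEVICE_RANGES = {
    "MP3": {"raw": (0.0, 34.0), "adjusted": (0.0, 34.0)},
    "MAIA": {"raw": (-1.0, 36.0), "adjusted": (0.0, 36.0)},
}


def adjust_sensitivity(raw_db: float, device: str,
                       config: QuantConfig | None = None) -> float:
    """Map a raw exported sensitivity to the analysis scale.

    MAIA exports may contain -1 dB; with ``maia_floor_adjust`` these are
    mapped to 0 dB so both devices share a 0-based floor. Values outside
    the device's raw range are a data error.
    """
    if config is None:
        config = QuantConfig()
    if device not in DEVICE_RANGES:
        raise ValueError(f"unknown device {device!r}")
    lo, hi = DEVICE_RANGES[device]["raw"]
    if not (lo <= raw_db <= hi):
        raise ValueError(f"{device} sensitivity {raw_db} outside raw range [{lo}, {hi}]")
    adj_lo, adj_hi = DEVICE_RANGES[device]["adjusted"]
    if device == "MAIA" and config.maia_floor_adjust and raw_db < 0:
        return 0.0
    return float(min(max(raw_db, adj_lo), adj_hi))
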