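"""Synthetic eye generation: en-face biomarker maps with known ground truth.

Maps live on the OCT en-face grid (rows = B-scans, columns = A-scans).
Drusen and subretinal deposits are additive radial bumps, hyperreflective
foci are sparse labelled components whose total volumes straddle the
0.06 nl filtering threshold, and layer thickness maps are smooth fields
with deposit-driven local thinning of the photoreceptor band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ..geometry import OCTGeometry


@dataclass(frozen=True)
class HRFComponent:
    """One connected hyperreflective-foci component.

    ``pixels`` are (bscan, ascan) en-face indices; each carries the voxel
    volume (nl) attributed to that column of the component.
    """

    component_id: int
    pixels: tuple[tuple[int, int], ...]
    voxel_volumes_nl: tuple[float, ...]

    @property
    def total_volume_nl(self) -> float:
        return float(sum(self.voxel_volumes_nl))


@dataclass
class BiomarkerMaps:
    """Ground-truth en-face rasters, all in um, plus labelled HRF."""

    ez_um: np.ndarray
    onl_um: np.ndarray
    drusen_height_um: np.ndarray
    sdd_height_um: np.ndarray
    hrf_components: list[HRFComponent]

    def validate(self, geometry: OCTGeometry) -> None:
        shape = geometry.shape
        for name in ("ez_um", "onl_um", "drusen_height_um", "sdd_height_um"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
        if np.any(self.ez_um > 60.0) or np.any(self.onl_um > 140.0):
            raise ValueError("thickness out of physiological range")
        for comp in self.hrf_components:
            if comp.total_volume_nl <= 0:
                raise ValueError("HRF component with non-positive volume")


@dataclass(frozen=True)
class VesselSegment:
    """Polyline in en-face um coordinates with a half-width in um."""

    points_um: np.ndarray  # (n, 2) as (x, y)
    radius_um: float


@dataclass
class VesselTree:
    segments: list[VesselSegment]
    junctions_um: np.ndarray  # (k, 2) ground-truth branch points (x, y)


@dataclass
class SyntheticEye:
    patient_id: str
    eye_side: str
    age_years: float
    maps: BiomarkerMaps
    vessels: VesselTree
    geometry: OCTGeometry

    @property
    def fovea_um(self) -> tuple[float, float]:
        return self.geometry.fovea_um


@dataclass(frozen=True)
class PhenotypeConfig:
    """Knobs of the synthetic phenotype. ``PhenotypeConfig.none()`` yields a
    deposit-free eye with flat 29 um EZ."""

    ez_base_um: float = 29.0
    ez_noise_um: float = 1.2
    ez_deposit_thinning: float = 0.22    # um EZ lost per um deposit height
    onl_center_um: float = 80.0
    onl_slope_um_per_deg: float = 5.0
    onl_noise_um: float = 2.5
    drusen_count_mean: float = 8.0
    drusen_height_um: tuple[float, float] = (20.0, 90.0)
    drusen_sigma_um: tuple[float, float] = (60.0, 190.0)
    drusen_radial_sigma_um: float = 850.0
    drusen_cutoff_um: float = 1.0
    sdd_prob: float = 0.65               # fraction of eyes with any SDD
    sdd_count_mean: float = 18.0
    sdd_height_um: tuple[float, float] = (14.0, 45.0)
    sdd_sigma_um: tuple[float, float] = (45.0, 130.0)
    sdd_ring_deg: tuple[float, float] = (3.6, 1.2)   # mean, sd of centre radius
    sdd_min_deg: float = 2.0
    sdd_cutoff_um: float = 0.5
    hrf_count_mean: float = 5.0
    hrf_log_volume: tuple[float, float] = (math.log(0.085), 0.55)
    hrf_extent_px: int = 3
    age_mean: float = 76.0
    age_sd: float = 7.0

    @classmethod
    def none(cls) -> "PhenotypeConfig":
        return cls(ez_noise_um=0.0, onl_noise_um=0.0, drusen_count_mean=0.0,
                   sdd_prob=0.0, hrf_count_mean=0.0)


def _radial_deg(geometry: OCTGeometry) -> np.ndarray:
    """Eccentricity (deg) of every en-face pixel centre from the fovea."""
    fx, fy = geometry.fovea_um
    x = np.arange(geometry.n_ascans) * geometry.ascan_spacing_um - fx
    y = np.arange(geometry.n_bscans) * geometry.bscan_spacing_um - fy
    X, Y = np.meshgrid(x, y)
    return np.hypot(X, Y) / geometry.um_per_deg


def _add_bump(target: np.ndarray, geometry: OCTGeometry, cx: float, cy: float,
              height: float, sigma: float, cutoff: float) -> None:
    """Add a truncated Gaussian bump in place, evaluated on a local window."""
    dx = geometry.ascan_spacing_um
    dy = geometry.bscan_spacing_um
    reach = sigma * math.sqrt(2.0 * math.log(max(height / cutoff, 1.000001)))
    a_lo = max(0, int((cx - reach) / dx))
    a_hi = min(geometry.n_ascans - 1, int(math.ceil((cx + reach) / dx)))
    b_lo = max(0, int((cy - reach) / dy))
    b_hi = min(geometry.n_bscans - 1, int(math.ceil((cy + reach) / dy)))
    if a_lo > a_hi or b_lo > b_hi:
        return
    ax = np.arange(a_lo, a_hi + 1) * dx - cx
    by = np.arange(b_lo, b_hi + 1) * dy - cy
    bump = height * np.exp(-(ax[None, :] ** 2 + by[:, None] ** 2) / (2.0 * sigma ** 2))
    bump[bump < cutoff] = 0.0
    target[b_lo:b_hi + 1, a_lo:a_hi + 1] += bump


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, geometry: OCTGeometry,
                  corr_um: float = 300.0) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sig_b = corr_um / geometry.bscan_spacing_um
    sig_a = corr_um / geometry.ascan_spacing_um
    sm = gaussian_filter(white, sigma=(sig_b, sig_a), mode="reflect")
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def _make_drusen(rng, geometry, cfg: PhenotypeConfig) -> np.ndarray:
    h = np.zeros(geometry.shape)
    n = rng.poisson(cfg.drusen_count_mean)
    fx, fy = geometry.fovea_um
    for _ in range(n):
        cx = fx + rng.normal(0.0, cfg.drusen_radial_sigma_um)
        cy = fy + rng.normal(0.0, cfg.drusen_radial_sigma_um)
        height = rng.uniform(*cfg.drusen_height_um)
        sigma = rng.uniform(*cfg.drusen_sigma_um)
        _add_bump(h, geometry, cx, cy, height, sigma, cfg.drusen_cutoff_um)
    return h


def _make_sdd(rng, geometry, cfg: PhenotypeConfig) -> np.ndarray:
    h = np.zeros(geometry.shape)
    if rng.uniform() >= cfg.sdd_prob:
        return h
    n = rng.poisson(cfg.sdd_count_mean)
    fx, fy = geometry.fovea_um
    for _ in range(n):
        r_deg = max(cfg.sdd_min_deg, rng.normal(*cfg.sdd_ring_deg))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cx = fx + r_deg * geometry.um_per_deg * math.cos(theta)
        cy = fy + r_deg * geometry.um_per_deg * math.sin(theta)
        height = rng.uniform(*cfg.sdd_height_um)
        sigma = rng.uniform(*cfg.sdd_sigma_um)
        _add_bump(h, geometry, cx, cy, height, sigma, cfg.sdd_cutoff_um)
    return h


def _make_hrf(rng, geometry, cfg: PhenotypeConfig) -> list[HRFComponent]:
    comps: list[HRFComponent] = []
    n = rng.poisson(cfg.hrf_count_mean)
    max_deg = min(geometry.field_deg) / 2.0 - 1.0
    fx, fy = geometry.fovea_um
    for cid in range(n):
        r_deg = rng.uniform(0.0, max_deg * 0.7)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cx = fx + r_deg * geometry.um_per_deg * math.cos(theta)
        cy = fy + r_deg * geometry.um_per_deg * math.sin(theta)
        b0 = int(round(cy / geometry.bscan_spacing_um))
        a0 = int(round(cx / geometry.ascan_spacing_um))
        ext = cfg.hrf_extent_px
        pix = []
        for db in range(-1, 2):
            for da in range(-ext, ext + 1):
                b, a = b0 + db, a0 + da
                if 0 <= b < geometry.n_bscans and 0 <= a < geometry.n_ascans:
                    pix.append((b, a))
        if not pix:
            continue
        total = float(np.exp(rng.normal(*cfg.hrf_log_volume)))
        w = rng.dirichlet(np.ones(len(pix)))
        comps.append(HRFComponent(cid, tuple(pix), tuple(float(total * wi) for wi in w)))
    return comps


def generate_eye(seed: int | np.random.Generator,
                 geometry: OCTGeometry | None = None,
                 phenotype: PhenotypeConfig | None = None,
                 patient_id: str = "P000",
                 eye_side: str = "OD") -> SyntheticEye:
    """Generate one synthetic eye with reproducible ground truth.

    All randomness flows from ``seed``; identical seeds give bit-identical
    maps. EZ is locally thinned where drusen or SDD are present, and the
    ONL baseline decreases with eccentricity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if geometry is None:
        geometry = OCTGeometry()
    if phenotype is None:
        phenotype = PhenotypeConfig()

    r_deg = _radial_deg(geometry)
    drusen = _make_drusen(rng, geometry, phenotype)
    sdd = _make_sdd(rng, geometry, phenotype)
    hrf = _make_hrf(rng, geometry, phenotype)

    onl = (phenotype.onl_center_um - phenotype.onl_slope_um_per_deg * r_deg
           + _smooth_noise(rng, geometry.shape, phenotype.onl_noise_um, geometry))
    ez = (phenotype.ez_base_um
          + _smooth_noise(rng, geometry.shape, phenotype.ez_noise_um, geometry)
          - phenotype.ez_deposit_thinning * (drusen + sdd))
    onl = np.clip(onl, 0.0, 140.0)
    ez = np.clip(ez, 0.0, 60.0)

    vessels = _generate_vessel_tree(rng, geometry)
    age = float(np.clip(rng.normal(phenotype.age_mean, phenotype.age_sd), 55.0, 95.0))
    maps = BiomarkerMaps(ez_um=ez, onl_um=onl, drusen_height_um=drusen,
                         sdd_height_um=sdd, hrf_components=hrf)
    maps.validate(geometry)
    return SyntheticEye(patient_id=patient_id, eye_side=eye_side, age_years=age,
                        maps=maps, vessels=vessels, geometry=geometry)


def _generate_vessel_tree(rng: np.random.Generator,
                          geometry: OCTGeometry) -> VesselTree:
    """Random branching vasculature entering from one side of the field.

    Branches are smoothed random walks; every bifurcation is recorded as a
    ground-truth junction. The macular centre is kept relatively avascular.
    """
    fx, fy = geometry.field_um
    fovea = np.array(geometry.fovea_um)
    segments: list[VesselSegment] = []
    junctions: list[np.ndarray] = []

    def grow(start: np.ndarray, direction: np.ndarray, radius: float,
             length: float, depth: int) -> None:
        step = 80.0
        n_steps = max(3, int(length / step))
        pts = [start.copy()]
        d = direction / (np.linalg.norm(direction) + 1e-12)
        p = start.copy()
        for _ in range(n_steps):
            # steer gently away from the fovea to keep the macula sparse
            away = p - fovea
            dist = np.linalg.norm(away)
            steer = away / dist * 0.25 if 0 < dist < 1500.0 else 0.0
            ang = rng.normal(0.0, 0.18)
            rot = np.array([[math.cos(ang), -math.sin(ang)],
                            [math.sin(ang), math.cos(ang)]])
            d = rot @ d + steer
            d /= np.linalg.norm(d) + 1e-12
            p = p + d * step
            pts.append(p.copy())
            if not (-400 <= p[0] <= fx + 400 and -400 <= p[1] <= fy + 400):
                break
        segments.append(VesselSegment(np.array(pts), radius))
        if depth > 0 and len(pts) >= 4:
            k = rng.integers(2, len(pts) - 1)
            branch_pt = pts[k]
            junctions.append(np.array(branch_pt))
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            ang = sign * rng.uniform(0.45, 1.0)
            rot = np.array([[math.cos(ang), -math.sin(ang)],
                            [math.sin(ang), math.cos(ang)]])
            tang = pts[min(k + 1, len(pts) - 1)] - pts[k - 1]
            grow(np.array(branch_pt), rot @ tang, radius * 0.75,
                 length * rng.uniform(0.5, 0.8), depth - 1)
            if rng.uniform() < 0.5 and len(pts) - k > 3:
                k2 = rng.integers(k + 1, len(pts))
                junctions.append(np.array(pts[k2]))
                ang2 = -sign * rng.uniform(0.45, 1.0)
                rot2 = np.array([[math.cos(ang2), -math.sin(ang2)],
                                 [math.sin(ang2), math.cos(ang2)]])
                grow(np.array(pts[k2]), rot2 @ tang, radius * 0.7,
                     length * rng.uniform(0.4, 0.7), depth - 1)

    n_roots = 4
    for i in range(n_roots):
        y0 = fy * (0.12 + 0.76 * i / (n_roots - 1)) + rng.normal(0.0, 150.0)
        start = np.array([0.0, y0])
        direction = np.array([1.0, rng.normal(0.0, 0.25)])
        grow(start, direction, radius=rng.uniform(28.0, 40.0),
             length=fx * rng.uniform(0.8, 1.1), depth=3)

    j = np.array(junctions) if junctions else np.empty((0, 2))
    return VesselTree(segments=segments, junctions_um=j)
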