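"""Cohort simulation: eyes plus four microperimetry acquisitions per patient.

Each patient contributes one eye tested twice on each of two devices
(photopic MP-3, 0-34 dB; mesopic MAIA, 0-36 dB with a raw -1 floor).
Device order is randomized per patient; run 2 re-tests the identical grid
via the follow-up function. Two measurement modes exist: ``direct``
(linear model + Gaussian noise) and ``psychophysical`` (full 4-2
staircase with a stochastic observer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..geometry import OCTGeometry
from ..quantify.discs import DEVICE_RANGES, QuantConfig
from ..register.transform import SimilarityTransform
from .eye import PhenotypeConfig, SyntheticEye, generate_eye
from .grid import GridLayout, StimulusGrid, build_stimulus_grid
from .sensitivity import SensitivityModel, point_features
from .staircase import ObserverModel, StaircaseConfig, run_staircase

DEVICES = ("MP3", "MAIA")

#: nominal device fundus scale (um of retina per image pixel) and image size
DEVICE_IMAGING = {
    "MP3": {"um_per_px": 10.0, "image_shape": (640, 640)},
    "MAIA": {"um_per_px": 9.0, "image_shape": (700, 700)},
}


@dataclass
class AcquisitionRecord:
    """One device exam: measured sensitivities plus hidden ground truth."""

    patient_id: str
    eye_side: str
    device: str                      # "MP3" | "MAIA"
    run: int                         # 1 | 2
    point_ids: np.ndarray            # (45,)
    stimulus_px: np.ndarray          # (45, 2) device-pixel coordinates
    measured_db: np.ndarray          # (45,) raw device export values
    true_transform: SimilarityTransform   # device-px -> oct-enface-um
    fundus: np.ndarray | None = None      # device raster (uint8), optional

    def __post_init__(self) -> None:
        lo, hi = DEVICE_RANGES[self.device]["raw"]
        if np.any(self.measured_db < lo - 1e-9) or np.any(self.measured_db > hi + 1e-9):
            raise ValueError(f"measured dB outside {self.device} raw range")


@dataclass
class PatientSim:
    eye: SyntheticEye
    patient_effect_db: float
    device_order: tuple[str, str]
    acquisitions: list[AcquisitionRecord]
    nir_image: np.ndarray | None = None   # OCT-NIR raster (uint8), optional
    nir_um_per_px: float = 11.25


@dataclass
class CohortSim:
    patients: list[PatientSim]
    grid: StimulusGrid
    geometry: OCTGeometry
    model: SensitivityModel
    mode: str

    @property
    def n_pws(self) -> int:
        return sum(len(a.measured_db) for p in self.patients for a in p.acquisitions)


def _sample_true_transform(rng: np.random.Generator, device: str,
                           geometry: OCTGeometry) -> SimilarityTransform:
    """Hidden device-pixel -> en-face-um similarity for one acquisition."""
    imaging = DEVICE_IMAGING[device]
    scale = imaging["um_per_px"] * rng.uniform(0.93, 1.07)
    rot = math.radians(rng.normal(0.0, 3.0))
    h, w = imaging["image_shape"]
    center_px = np.array([w / 2.0, h / 2.0])
    fovea = np.array(geometry.fovea_um)
    jitter = rng.normal(0.0, 120.0, size=2)
    c, s = math.cos(rot), math.sin(rot)
    R = np.array([[c, -s], [s, c]])
    t = fovea + jitter - scale * (R @ center_px)
    return SimilarityTransform(scale, rot, (float(t[0]), float(t[1])))


def simulate_cohort(n_patients: int, seed: int = 0,
                    geometry: OCTGeometry | None = None,
                    layout: GridLayout | None = None,
                    model: SensitivityModel | None = None,
                    phenotype: PhenotypeConfig | None = None,
                    observer: ObserverModel | None = None,
                    mode: str = "direct",
                    quant: QuantConfig | None = None,
                    render_fundus: bool = False) -> CohortSim:
    """Simulate ``n_patients`` eyes with 2 devices x 2 runs each.

    Determinism: the full cohort, including any rendered images, is a pure
    function of ``seed`` and the configs. Total PWS count is
    ``n_patients * n_points * 4``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if mode not in ("direct", "psychophysical"):
        raise ValueError("mode must be 'direct' or 'psychophysical'")
    if geometry is None:
        geometry = OCTGeometry()
    if model is None:
        model = SensitivityModel()
    if phenotype is None:
        phenotype = PhenotypeConfig()
    if observer is None:
        observer = ObserverModel()
    if quant is None:
        quant = QuantConfig()
    grid = build_stimulus_grid(layout)

    from .fundus import render_fundus_images  # local import, avoids cycle

    root = np.random.SeedSequence(seed)
    patients: list[PatientSim] = []
    for i, ss in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(ss)
        pid = f"P{i:03d}"
        eye = generate_eye(rng, geometry, phenotype, patient_id=pid,
                           eye_side="OD" if rng.uniform() < 0.5 else "OS")
        patient_effect = float(rng.normal(0.0, model.random_intercept_sd_db))
        order = DEVICES if rng.uniform() < 0.5 else DEVICES[::-1]

        positions = grid.enface_positions_um(geometry)
        feats = [point_features(eye.maps, p, geometry, quant) for p in positions]
        point_ids = np.array(grid.point_ids)

        nir_image = None
        nir_um_per_px = geometry.ascan_spacing_um
        acquisitions: list[AcquisitionRecord] = []
        for device in order:
            # same retinal locations on both runs (device follow-up function)
            for run in (1, 2):
                T = _sample_true_transform(rng, device, geometry)
                stim_px = T.inverse().apply(np.array(positions))
                cfg = StaircaseConfig.mp3() if device == "MP3" else StaircaseConfig.maia()
                thresholds = np.array([
                    model.linear_predictor(device=device, run=run,
                                           age=eye.age_years, **f)
                    + patient_effect
                    for f in feats
                ])
                if mode == "direct":
                    vals = thresholds + rng.normal(0.0, model.residual_sd_db,
                                                   size=len(thresholds))
                    vals = np.clip(vals, cfg.min_db, cfg.max_db)
                else:
                    vals = np.array([
                        run_staircase(t + rng.normal(0.0, model.residual_sd_db)
                                      if model.residual_sd_db > 0 else t,
                                      observer, cfg, rng)
                        for t in thresholds
                    ])
                fundus = None
                if render_fundus:
                    fundus, nir_candidate = render_fundus_images(
                        eye.vessels, geometry, device, T, rng)
                    if nir_image is None:
                        nir_image = nir_candidate
                acquisitions.append(AcquisitionRecord(
                    patient_id=pid, eye_side=eye.eye_side, device=device,
                    run=run, point_ids=point_ids, stimulus_px=stim_px,
                    measured_db=vals, true_transform=T, fundus=fundus))
        patients.append(PatientSim(eye=eye, patient_effect_db=patient_effect,
                                   device_order=tuple(order),
                                   acquisitions=acquisitions,
                                   nir_image=nir_image,
                                   nir_um_per_px=nir_um_per_px))
    return CohortSim(patients=patients, grid=grid, geometry=geometry,
                     model=model, mode=mode)
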