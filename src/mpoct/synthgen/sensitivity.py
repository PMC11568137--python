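"""Linear sensitivity model: ground-truth point-wise thresholds.

The true threshold at a stimulus is a linear combination of the biomarkers
quantified in its 70 um disc, with eccentricity-dependent slopes for the
photoreceptor-band and outer-nuclear-layer thickness terms, a device shift,
and a per-patient random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..geometry import OCTGeometry
from ..quantify.discs import (QuantConfig, disc_pixels, eccentricity_deg,
                              hrf_volume_in_disc, mean_thickness,
                              volume_in_disc)


@dataclass(frozen=True)
class SensitivityModel:
    """Coefficients of the generating linear model (dB units).

    Defaults are the published final-model estimates where available;
    terms dropped during model selection (run, age, SDD) default to 0.
    The intercept and the two variance components are calibration choices
    so that device-level means and the marginal R^2 land in the reported
    range.
    """

    intercept_db: float = 21.9
    device_offset_db: float = -3.553     # MAIA relative to MP-3
    run_offset_db: float = 0.0
    age_slope_db_per_year: float = 0.0
    beta_drusen_db_per_nl: float = -0.632
    beta_hrf_db_per_nl: float = -9.535
    beta_sdd_db_per_nl: float = 0.0
    beta_onl_db_per_um: float = 0.016    # at 0 deg
    beta_ez_db_per_um: float = 0.148     # at 0 deg
    beta_onl_ecc: float = 0.008          # dB/um/deg
    beta_ez_ecc: float = -0.025          # dB/um/deg
    random_intercept_sd_db: float = 1.7
    residual_sd_db: float = 2.4

    def __post_init__(self) -> None:
        if self.random_intercept_sd_db < 0 or self.residual_sd_db < 0:
            raise ValueError("standard deviations must be >= 0")

    def linear_predictor(self, *, device: str, run: int, age: float,
                         eccentricity_deg: float, ez_um: float, onl_um: float,
                         drusen_nl: float, sdd_nl: float, hrf_nl: float) -> float:
        r = eccentricity_deg
        return (self.intercept_db
                + self.device_offset_db * (1.0 if device == "MAIA" else 0.0)
                + self.run_offset_db * (1.0 if run == 2 else 0.0)
                + self.age_slope_db_per_year * age
                + self.beta_drusen_db_per_nl * drusen_nl
                + self.beta_hrf_db_per_nl * hrf_nl
                + self.beta_sdd_db_per_nl * sdd_nl
                + (self.beta_onl_db_per_um + r * self.beta_onl_ecc) * onl_um
                + (self.beta_ez_db_per_um + r * self.beta_ez_ecc) * ez_um)


def point_features(maps, point_xy_um: tuple[float, float],
                   geometry: OCTGeometry,
                   quant: QuantConfig | None = None) -> dict[str, float]:
    """Quantify all biomarkers of one stimulus disc on ground-truth maps."""
    if quant is None:
        quant = QuantConfig()
    disc = disc_pixels(point_xy_um, geometry, quant.radius_um)
    return {
        "eccentricity_deg": eccentricity_deg(point_xy_um, geometry.fovea_um, geometry),
        "ez_um": mean_thickness(maps.ez_um, disc),
        "onl_um": mean_thickness(maps.onl_um, disc),
        "drusen_nl": volume_in_disc(maps.drusen_height_um, disc, geometry),
        "sdd_nl": volume_in_disc(maps.sdd_height_um, disc, geometry),
        "hrf_nl": hrf_volume_in_disc(maps.hrf_components, disc, quant),
    }


def true_threshold(maps, point_xy_um: tuple[float, float],
                   geometry: OCTGeometry, model: SensitivityModel,
                   device: str, patient_effect_db: float = 0.0,
                   run: int = 1, age: float = 0.0,
                   quant: QuantConfig | None = None) -> float:
    """Ground-truth threshold (dB) for one stimulus on one device.

    Features are quantified on the ground-truth maps with the same disc
    machinery used downstream, so the generating model and the analysis
    model see identical covariates.
    """
    feats = point_features(maps, point_xy_um, geometry, quant)
    return model.linear_predictor(device=device, run=run, age=age,
                                  **feats) + patient_effect_db
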