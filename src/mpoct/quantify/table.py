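"""Long-format analysis table: one row per patient x device x run x point.

Each acquisition is registered independently; its stimulus pixel
coordinates are mapped into the en-face frame by the acquisition's
similarity transform, quantified within the stimulus disc and combined
with the adjusted sensitivity into an analysis record. Stimuli whose
centre falls outside the scanned area are flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..geometry import OCTGeometry
from ..register.transform import SimilarityTransform
from .discs import (QuantConfig, adjust_sensitivity, disc_pixels,
                    eccentricity_deg, hrf_volume_in_disc, mean_thickness,
                    volume_in_disc)

#: fixed output column order of the analysis table
TABLE_COLUMNS = [
    "patient_id", "device", "run", "point_id", "eccentricity_deg", "age",
    "ez_um", "onl_um", "drusen_nl", "sdd_nl", "hrf_nl", "pws_db", "included",
]


class MissingRegistrationError(KeyError):
    pass


def quantify_acquisition(record, maps, geometry: OCTGeometry,
                         transform: SimilarityTransform, age: float,
                         quant: QuantConfig | None = None) -> pd.DataFrame:
    """Analysis records for one acquisition under a given registration."""
    if quant is None:
        quant = QuantConfig()
    fovea = geometry.fovea_um
    positions = transform.apply(record.stimulus_px)
    rows = []
    for (pid_pt, (x, y), raw) in zip(record.point_ids, positions,
                                     record.measured_db):
        included = geometry.contains(x, y)
        if included:
            disc = disc_pixels((x, y), geometry, quant.radius_um)
            row = dict(
                eccentricity_deg=eccentricity_deg((x, y), fovea, geometry),
                ez_um=mean_thickness(maps.ez_um, disc),
                onl_um=mean_thickness(maps.onl_um, disc),
                drusen_nl=volume_in_disc(maps.drusen_height_um, disc, geometry),
                sdd_nl=volume_in_disc(maps.sdd_height_um, disc, geometry),
                hrf_nl=hrf_volume_in_disc(maps.hrf_components, disc, quant),
            )
        else:
            row = dict(eccentricity_deg=np.nan, ez_um=np.nan, onl_um=np.nan,
                       drusen_nl=np.nan, sdd_nl=np.nan, hrf_nl=np.nan)
        rows.append(dict(
            patient_id=record.patient_id, device=record.device,
            run=record.run, point_id=int(pid_pt), age=age,
            pws_db=adjust_sensitivity(float(raw), record.device, quant),
            included=bool(included), **row))
    return pd.DataFrame(rows)[TABLE_COLUMNS]


def assemble_table(cohort, registrations: dict | None = None,
                   quant: QuantConfig | None = None) -> pd.DataFrame:
    """Assemble the full long table for a simulated cohort.

    ``registrations`` maps ``(patient_id, device, run)`` to the estimated
    device-px -> en-face-um transform; ``None`` falls back to the hidden
    true transforms (oracle registration). A missing key for any
    acquisition is a hard error.
    """
    frames = []
    for p in cohort.patients:
        for a in p.acquisitions:
            if registrations is None:
                T = a.true_transform
            else:
                key = (a.patient_id, a.device, a.run)
                if key not in registrations:
                    raise MissingRegistrationError(
                        f"no registration for acquisition {key}")
                T = registrations[key]
            frames.append(quantify_acquisition(
                a, p.eye.maps, cohort.geometry, T, p.eye.age_years, quant))
    table = pd.concat(frames, ignore_index=True)
    return table


def included_count(table: pd.DataFrame) -> int:
    return int(table["included"].sum())
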