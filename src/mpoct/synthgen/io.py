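"""Acquisition and eye export in the device/OCT interchange layout.

Layout per acquisition (``<patient>_<device>_run<run>/``):

* ``stimuli.csv`` — ``point_id,x_px,y_px,sensitivity_db`` (raw device
  values; a MAIA -1 is stored as-is, adjustment happens at quantification)
* ``fundus.png`` — 8-bit grayscale device raster (if rendered)
* ``meta.json`` — patient/device/run plus the hidden true transform
  (kept for evaluation only)

Per eye (``<patient>_oct/``): one CSV per en-face map (row = B-scan,
column = A-scan), ``hrf.csv`` with labelled component voxels, and
``geometry.json``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from ..geometry import OCTGeometry
from ..register.transform import SimilarityTransform
from .cohort import AcquisitionRecord
from .eye import BiomarkerMaps, HRFComponent

_MAP_FILES = {
    "ez_um": "ez.csv",
    "onl_um": "onl.csv",
    "drusen_height_um": "drusen_height.csv",
    "sdd_height_um": "sdd_height.csv",
}


def export_acquisition(record: AcquisitionRecord, out_dir: str | Path) -> Path:
    """Write one acquisition; returns its directory."""
    d = Path(out_dir) / f"{record.patient_id}_{record.device}_run{record.run}"
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "stimuli.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id", "x_px", "y_px", "sensitivity_db"])
        for pid, (x, y), db in zip(record.point_ids, record.stimulus_px,
                                   record.measured_db):
            w.writerow([int(pid), repr(float(x)), repr(float(y)),
                        repr(float(db))])
    if record.fundus is not None:
        Image.fromarray(record.fundus, mode="L").save(d / "fundus.png")
    meta = {
        "patient_id": record.patient_id,
        "eye_side": record.eye_side,
        "device": record.device,
        "run": record.run,
        "true_transform": {
            "scale": record.true_transform.scale,
            "rotation_rad": record.true_transform.rotation_rad,
            "translation": list(record.true_transform.translation),
        },
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


def import_acquisition(acq_dir: str | Path) -> AcquisitionRecord:
    d = Path(acq_dir)
    meta = json.loads((d / "meta.json").read_text())
    pids, px, db = [], [], []
    with open(d / "stimuli.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pids.append(int(row["point_id"]))
            px.append((float(row["x_px"]), float(row["y_px"])))
            db.append(float(row["sensitivity_db"]))
    fundus = None
    if (d / "fundus.png").exists():
        fundus = np.asarray(Image.open(d / "fundus.png"), dtype=np.uint8)
    tt = meta["true_transform"]
    return AcquisitionRecord(
        patient_id=meta["patient_id"], eye_side=meta["eye_side"],
        device=meta["device"], run=int(meta["run"]),
        point_ids=np.array(pids), stimulus_px=np.array(px),
        measured_db=np.array(db),
        true_transform=SimilarityTransform(tt["scale"], tt["rotation_rad"],
                                           tuple(tt["translation"])),
        fundus=fundus)


def export_eye_maps(maps: BiomarkerMaps, geometry: OCTGeometry,
                    patient_id: str, out_dir: str | Path) -> Path:
    d = Path(out_dir) / f"{patient_id}_oct"
    d.mkdir(parents=True, exist_ok=True)
    for attr, fname in _MAP_FILES.items():
        np.savetxt(d / fname, getattr(maps, attr), delimiter=",")
    with open(d / "hrf.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component_id", "bscan", "ascan", "voxel_volume_nl"])
        for comp in maps.hrf_components:
            for (b, a), v in zip(comp.pixels, comp.voxel_volumes_nl):
                w.writerow([comp.component_id, b, a, repr(float(v))])
    geo = {
        "n_bscans": geometry.n_bscans, "n_ascans": geometry.n_ascans,
        "field_deg": list(geometry.field_deg),
        "um_per_deg": geometry.um_per_deg,
        "fovea_xy_um": (list(geometry.fovea_xy_um)
                        if geometry.fovea_xy_um is not None else None),
    }
    (d / "geometry.json").write_text(json.dumps(geo, indent=2))
    return d


def import_eye_maps(eye_dir: str | Path) -> tuple[BiomarkerMaps, OCTGeometry]:
    d = Path(eye_dir)
    geo = json.loads((d / "geometry.json").read_text())
    geometry = OCTGeometry(
        n_bscans=geo["n_bscans"], n_ascans=geo["n_ascans"],
        field_deg=tuple(geo["field_deg"]), um_per_deg=geo["um_per_deg"],
        fovea_xy_um=tuple(geo["fovea_xy_um"]) if geo["fovea_xy_um"] else None)
    arrays = {attr: np.loadtxt(d / fname, delimiter=",", ndmin=2)
              for attr, fname in _MAP_FILES.items()}
    comps: dict[int, list[tuple[int, int, float]]] = {}
    with open(d / "hrf.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            comps.setdefault(int(row["component_id"]), []).append(
                (int(row["bscan"]), int(row["ascan"]),
                 float(row["voxel_volume_nl"])))
    components = [
        HRFComponent(cid, tuple((b, a) for b, a, _ in vox),
                     tuple(v for _, _, v in vox))
        for cid, vox in sorted(comps.items())
    ]
    maps = BiomarkerMaps(ez_um=arrays["ez_um"], onl_um=arrays["onl_um"],
                         drusen_height_um=arrays["drusen_height_um"],
                         sdd_height_um=arrays["sdd_height_um"],
                         hrf_components=components)
    return maps, geometry
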