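"""Rasterization of the synthetic vessel tree into fundus-like images.

Two modalities are produced per acquisition: the OCT-NIR raster in the
en-face frame and the device raster (MP-3 colour-fundus-like or MAIA-NIR)
in device pixels under the hidden similarity transform. Vessels are dark
on a brighter background; modalities differ in contrast and noise level.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..geometry import OCTGeometry
from ..register.transform import SimilarityTransform


def rasterize_vessels(vessels, um_to_px: SimilarityTransform,
                      shape: tuple[int, int]) -> np.ndarray:
    """Binary vessel mask in a pixel frame given the um -> px transform."""
    if um_to_px.scale <= 1e-9:
        raise ValueError("degenerate (near-zero scale) transform")
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[-12:13, -12:13]
    for seg in vessels.segments:
        pts_px = um_to_px.apply(seg.points_um)
        radius_px = max(1.0, seg.radius_um * um_to_px.scale)
        r = int(np.ceil(radius_px))
        if r > 12:
            r = 12
        disk_dy = yy[12 - r:13 + r, 12 - r:13 + r]
        disk_dx = xx[12 - r:13 + r, 12 - r:13 + r]
        disk = disk_dx ** 2 + disk_dy ** 2 <= radius_px ** 2
        ddy = disk_dy[disk]
        ddx = disk_dx[disk]
        # densely resample the polyline so consecutive samples are < 1 px apart
        for p, q in zip(pts_px[:-1], pts_px[1:]):
            n = int(np.ceil(np.hypot(*(q - p)))) + 1
            ts = np.linspace(0.0, 1.0, n)
            xs = np.rint(p[0] + ts * (q[0] - p[0])).astype(int)
            ys = np.rint(p[1] + ts * (q[1] - p[1])).astype(int)
            for cx, cy in zip(xs, ys):
                px = cx + ddx
                py = cy + ddy
                ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
                mask[py[ok], px[ok]] = True
    return mask


def _shade(mask: np.ndarray, rng: np.random.Generator, contrast: float,
           noise_sd: float, background: float) -> np.ndarray:
    soft = gaussian_filter(mask.astype(float), sigma=0.8)
    img = background - contrast * np.clip(soft, 0.0, 1.0)
    h, w = mask.shape
    gx = np.linspace(-1.0, 1.0, w)[None, :]
    gy = np.linspace(-1.0, 1.0, h)[:, None]
    img = img + 0.04 * gx + 0.03 * gy * gx  # mild illumination field
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=mask.shape)
    return np.clip(img * 255.0, 0, 255).astype(np.uint8)


#: per-modality contrast/noise; MP-3 CFP is flatter and noisier than NIR
MODALITY_PARAMS = {
    "NIR": {"contrast": 0.45, "noise_sd": 0.03, "background": 0.70},
    "MP3": {"contrast": 0.30, "noise_sd": 0.05, "background": 0.62},
    "MAIA": {"contrast": 0.42, "noise_sd": 0.04, "background": 0.68},
}


def render_fundus_images(vessels, geometry: OCTGeometry, device: str,
                         true_transform: SimilarityTransform,
                         rng: np.random.Generator,
                         noise: bool = True):
    """Render the (device raster, OCT-NIR raster) pair for one acquisition.

    The NIR raster lives in the en-face frame at the A-scan pixel pitch;
    the device raster is the same vessel tree seen through the hidden
    device-px -> en-face-um similarity. The transform is ground truth for
    evaluation only and is never given to the registration stage.
    """
    from .cohort import DEVICE_IMAGING  # local import avoids a cycle

    nir_um_per_px = geometry.ascan_spacing_um
    nir_shape = (int(round(geometry.field_um[1] / nir_um_per_px)) + 1,
                 geometry.n_ascans)
    nir_mask = rasterize_vessels(
        vessels, SimilarityTransform(1.0 / nir_um_per_px, 0.0, (0.0, 0.0)),
        nir_shape)
    dev_shape = DEVICE_IMAGING[device]["image_shape"]
    dev_mask = rasterize_vessels(vessels, true_transform.inverse(), dev_shape)

    p_nir = MODALITY_PARAMS["NIR"]
    p_dev = MODALITY_PARAMS[device]
    sd_n = p_nir["noise_sd"] if noise else 0.0
    sd_d = p_dev["noise_sd"] if noise else 0.0
    nir_img = _shade(nir_mask, rng, p_nir["contrast"], sd_n, p_nir["background"])
    dev_img = _shade(dev_mask, rng, p_dev["contrast"], sd_d, p_dev["background"])
    return dev_img, nir_img
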