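"""OCT acquisition geometry: en-face grid, pixel spacing and coordinate frames.

The en-face frame has its origin at the scan corner, ``x`` along the A-scan
axis (columns) and ``y`` along the B-scan axis (rows), both in micrometres.
Pixel centres span the full field extent, i.e. spacing = extent / (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OCTGeometry:
    """Macular cube geometry.

    Defaults describe a 97-B-scan cube over a 20 x 20 degree field at a
    retinal scale of 288 um/degree, which yields ~60 um between B-scans and
    ~11.3 um between A-scans.
    """

    n_bscans: int = 97
    n_ascans: int = 512
    field_deg: tuple[float, float] = (20.0, 20.0)  # (x extent, y extent)
    um_per_deg: float = 288.0
    fovea_xy_um: tuple[float, float] | None = None  # None -> field centre

    def __post_init__(self) -> None:
        if self.n_bscans < 2 or self.n_ascans < 2:
            raise ValueError("raster must be at least 2 x 2")
        if self.field_deg[0] <= 0 or self.field_deg[1] <= 0 or self.um_per_deg <= 0:
            raise ValueError("field extent and retinal scale must be positive")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_deg[0] * self.um_per_deg, self.field_deg[1] * self.um_per_deg)

    @property
    def ascan_spacing_um(self) -> float:
        return self.field_um[0] / (self.n_ascans - 1)

    @property
    def bscan_spacing_um(self) -> float:
        return self.field_um[1] / (self.n_bscans - 1)

    @property
    def pixel_area_um2(self) -> float:
        return self.ascan_spacing_um * self.bscan_spacing_um

    @property
    def fovea_um(self) -> tuple[float, float]:
        if self.fovea_xy_um is not None:
            return self.fovea_xy_um
        return (self.field_um[0] / 2.0, self.field_um[1] / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as (n_bscans, n_ascans) = (rows, cols)."""
        return (self.n_bscans, self.n_ascans)

    def contains(self, x_um: float, y_um: float) -> bool:
        fx, fy = self.field_um
        return 0.0 <= x_um <= fx and 0.0 <= y_um <= fy
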