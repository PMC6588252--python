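"""Per-layer mean-value-fundus (MVF) images, orientation normalisation, and
ETDRS-sector retinal thickness.

The MVF image of a retinal layer is the en-face map whose pixel at (x, y)
is the mean A-scan intensity between the layer's two boundary surfaces at
that position.  All analysis downstream assumes right-eye orientation
(columns temporal → nasal), so left-eye images are mirrored once and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import LAYERS, LayerSurfaces, OCTVolume

ETDRS_CENTRAL_RADIUS_UM = 500.0
ETDRS_INNER_RADIUS_UM = 1500.0
ETDRS_OUTER_RADIUS_UM = 3000.0

SECTOR_NAMES = (
    "central",
    "nasal_inner", "temporal_inner", "superior_inner", "inferior_inner",
    "nasal_outer", "temporal_outer", "superior_outer", "inferior_outer",
)


@dataclass
class MVFImage:
    """En-face mean-value image of one retinal layer.

    ``values`` is indexed ``[y, x]`` (rows superior → inferior).  After
    ``normalise_orientation`` columns run temporal → nasal regardless of the
    source eye.
    """

    values: np.ndarray
    layer: str
    laterality: str
    normalised: bool = False
    voxel_scale: tuple[float, float] | None = None  # µm per pixel (x, y)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MVF values must be 2-D")


@dataclass
class ThicknessSectors:
    """Nine ETDRS sector mean thicknesses (µm)."""

    sectors: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(SECTOR_NAMES) - set(self.sectors)
        if missing:
            raise ValueError(f"missing sectors: {sorted(missing)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sectors[n] for n in SECTOR_NAMES])


def compute_mvf(volume: OCTVolume, surfaces: LayerSurfaces, layer: str) -> MVFImage:
    """Average the A-scan values between a layer's two boundary surfaces.

    The depth segment is half-open ``[upper, lower)`` in voxel index after
    rounding the boundary depths to the voxel grid; a zero-extent layer
    falls back to the single nearest boundary voxel.

    Raises
    ------
    ValueError
        If the boundaries cross (lower above upper), naming the first
        offending (x, y) position.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    upper_um, lower_um = surfaces.layer_interfaces(layer)
    ny, nx, nz = volume.intensity.shape
    if upper_um.shape != (ny, nx):
        raise ValueError("surfaces do not cover the volume grid")
    if np.any(lower_um < upper_um):
        yy, xx = np.argwhere(lower_um < upper_um)[0]
        raise ValueError(
            f"crossing boundaries for layer {layer} at (x={xx}, y={yy})"
        )
    sz = volume.voxel_scale[2]
    upper = np.clip(np.rint(upper_um / sz).astype(np.int64), 0, nz)
    lower = np.clip(np.rint(lower_um / sz).astype(np.int64), 0, nz)

    # Prefix sums along depth: segment mean in O(1) per A-scan.
    csum = np.concatenate(
        [np.zeros((ny, nx, 1)), np.cumsum(volume.intensity, axis=2)], axis=2
    )
    extent = lower - upper
    seg_sum = (
        np.take_along_axis(csum, lower[:, :, None], axis=2)
        - np.take_along_axis(csum, upper[:, :, None], axis=2)
    )[:, :, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = seg_sum / extent
    # zero-extent layer: nearest single voxel
    if np.any(extent <= 0):
        idx = np.clip(upper, 0, nz - 1)
        fallback = np.take_along_axis(volume.intensity, idx[:, :, None], axis=2)[:, :, 0]
        values = np.where(extent <= 0, fallback, values)
    sx, sy = volume.voxel_scale[0], volume.voxel_scale[1]
    return MVFImage(values, layer, volume.laterality, False, (sx, sy))


def normalise_orientation(image: MVFImage, laterality: str | None = None) -> MVFImage:
    """Mirror left-eye images about the vertical axis; right eyes pass through.

    Normalisation is recorded on the image and applying it twice is a usage
    error (mirroring an already-normalised image would silently re-swap the
    temporal/nasal sides).
    """
    if image.normalised:
        raise ValueError("image is already laterality-normalised")
    lat = laterality if laterality is not None else image.laterality
    values = image.values[:, ::-1].copy() if lat == "left" else image.values.copy()
    return MVFImage(values, image.layer, lat, True, image.voxel_scale)


def compute_total_thickness(
    surfaces: LayerSurfaces, voxel_scale=None
) -> np.ndarray:
    """Full retinal thickness map (µm): ILM to the top of the RPE."""
    return surfaces.boundary("RPE_TOP") - surfaces.boundary("ILM")


def compute_layer_thickness(surfaces: LayerSurfaces, layer: str) -> np.ndarray:
    """Single-layer thickness map (µm) between its two interfaces."""
    upper, lower = surfaces.layer_interfaces(layer)
    return lower - upper


def _sector_masks(
    shape: tuple[int, int],
    pixel_scale: tuple[float, float],
    fovea_centre: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Boolean masks of the nine ETDRS sectors over the en-face grid.

    Quadrants split at the ±45° diagonals; pixels exactly on a diagonal go
    to the horizontal (temporal/nasal) quadrants.  Temporal is the low-x
    side and superior the low-y side, i.e. right-eye orientation.
    """
    ny, nx = shape
    sx, sy = pixel_scale
    cx, cy = fovea_centre
    dx = (np.arange(nx) - cx) * sx
    dy = (np.arange(ny) - cy) * sy
    DX = np.broadcast_to(dx[None, :], (ny, nx))
    DY = np.broadcast_to(dy[:, None], (ny, nx))
    r = np.hypot(DX, DY)

    horiz = np.abs(DX) >= np.abs(DY)
    temporal = horiz & (DX < 0)
    nasal = horiz & (DX >= 0)
    superior = ~horiz & (DY < 0)
    inferior = ~horiz & (DY >= 0)

    central = r < ETDRS_CENTRAL_RADIUS_UM
    inner = (r >= ETDRS_CENTRAL_RADIUS_UM) & (r < ETDRS_INNER_RADIUS_UM)
    outer = (r >= ETDRS_INNER_RADIUS_UM) & (r < ETDRS_OUTER_RADIUS_UM)

    return {
        "central": central,
        "nasal_inner": inner & nasal,
        "temporal_inner": inner & temporal,
        "superior_inner": inner & superior,
        "inferior_inner": inner & inferior,
        "nasal_outer": outer & nasal,
        "temporal_outer": outer & temporal,
        "superior_outer": outer & superior,
        "inferior_outer": outer & inferior,
    }


def etdrs_sectors(
    thickness_map: np.ndarray,
    pixel_scale: tuple[float, float],
    fovea_centre: tuple[float, float] | None = None,
) -> ThicknessSectors:
    """Mean thickness in the nine ETDRS sectors around the fovea.

    Central disc radius 500 µm, inner annulus 500–1500 µm, outer annulus
    1500–3000 µm; annuli split into temporal/nasal/superior/inferior
    quadrants at the ±45° diagonals.  A pixel belongs to the sector that
    contains its centre.

    Raises
    ------
    ValueError
        If the grid does not reach the 3000 µm outer radius along both axes
        (1% slack is allowed, since a nominal 6x6 mm field sampled on a
        power-of-two grid falls a fraction of a pixel short).
    """
    thickness_map = np.asarray(thickness_map, dtype=float)
    ny, nx = thickness_map.shape
    sx, sy = pixel_scale
    if fovea_centre is None:
        fovea_centre = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = fovea_centre
    half_x = (min(cx, nx - 1 - cx) + 0.5) * sx
    half_y = (min(cy, ny - 1 - cy) + 0.5) * sy
    required = ETDRS_OUTER_RADIUS_UM * 0.99
    if half_x < required or half_y < required:
        raise ValueError(
            "grid does not cover the 3000 µm ETDRS outer radius around the fovea"
        )
    masks = _sector_masks((ny, nx), pixel_scale, fovea_centre)
    sectors = {name: float(thickness_map[m].mean()) for name, m in masks.items()}
    return ThicknessSectors(sectors)
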