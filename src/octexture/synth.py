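"""Synthetic OCT macular cohorts with class-conditional layer texture.

Generates volumes + layer surfaces for three groups (healthy controls,
Alzheimer's, Parkinson's) so the full fundus → texture → classification
pipeline can be exercised without patient data.  The generator emulates the
structure of a macular-cube acquisition: a 512x128 A-scan grid by default,
two eyes per subject with a tunable shared texture fraction, mirrored
left-eye geometry, and a radially symmetric foveal depression in the layer
surfaces.  It does not attempt OCT speckle physics, vessel shadows, or
device noise spectra.

Axis conventions
----------------
En-face arrays are indexed ``[y, x]`` with rows running superior → inferior
and columns temporal → nasal *for right eyes* (left eyes are stored
mirrored, i.e. nasal → temporal, and are un-mirrored downstream).  Volumes
are indexed ``[y, x, z]`` with ``z`` the depth (vitreous → choroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

#: Inner retinal layers carrying class-conditional texture, inner → outer.
LAYERS = ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL")

#: Boundary surfaces delimiting the layers, inner → outer.  ILM is the inner
#: limiting membrane; RPE_TOP the top of the retinal pigment epithelium.
BOUNDARIES = (
    "ILM",
    "RNFL_GCL",
    "GCL_IPL",
    "IPL_INL",
    "INL_OPL",
    "OPL_ONL",
    "ONL_BOTTOM",
    "RPE_TOP",
)

CLASSES = ("HC", "AD", "PD")

# Nominal per-layer thicknesses (µm), ILM → RPE top.  The implied total of
# 320 µm at the parafovea and ~230 µm at a 90 µm pit sit inside the range of
# published macular thickness maps for healthy adults.
_LAYER_THICKNESS_UM = {
    "RNFL": 35.0,
    "GCL": 40.0,
    "IPL": 35.0,
    "INL": 35.0,
    "OPL": 30.0,
    "ONL": 80.0,
    "PR": 65.0,  # ONL bottom → RPE top (photoreceptor complex)
}

_ILM_BASE_DEPTH_UM = 150.0

# Grey values for the non-textured compartments of the volume.
_VITREOUS_GREY = 10.0
_PR_GREY = 60.0
_BELOW_RPE_GREY = 30.0


@dataclass(frozen=True)
class LayerTextureParams:
    """Texture of one retinal layer for one class.

    ``correlation_length_x/y`` are in pixels of the en-face generation grid;
    anisotropy between them drives directional-subband differences in the
    wavelet features.  ``contrast_gain`` multiplies the local fluctuation
    amplitude on top of ``noise_sd``.
    """

    base_intensity: float = 100.0
    noise_sd: float = 12.0
    correlation_length_x: float = 8.0
    correlation_length_y: float = 2.0
    contrast_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.correlation_length_x <= 0 or self.correlation_length_y <= 0:
            raise ValueError("correlation lengths must be > 0")
        if not (0.0 <= self.base_intensity <= 255.0):
            raise ValueError("base_intensity outside representable grey range")


@dataclass(frozen=True)
class ClassTextureParams:
    """Per-layer texture parameters for one diagnostic class."""

    class_label: str
    layers: dict[str, LayerTextureParams] = field(
        default_factory=lambda: {lyr: LayerTextureParams() for lyr in LAYERS}
    )

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        missing = set(LAYERS) - set(self.layers)
        if missing:
            raise ValueError(f"missing layer params: {sorted(missing)}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort geometry and acquisition emulation parameters.

    grid
        ``(n_ascans_x, n_bscans_y, n_depth)`` voxels; the default mirrors a
        512x128 macular-cube protocol.
    voxel_scale
        µm per voxel along x, y, z.
    foveal_pit_depth
        Depth of the radially symmetric foveal depression (µm).
    within_subject_correlation
        Fraction in [0, 1] of each layer's texture field shared between a
        subject's two eyes.
    axial_noise_sd
        Independent per-voxel grey noise added to the volume.
    """

    n_subjects_per_class: int = 10
    grid: tuple[int, int, int] = (512, 128, 128)
    voxel_scale: tuple[float, float, float] = (11.7, 47.0, 3.9)
    foveal_pit_depth: float = 90.0
    pit_radius_um: float = 500.0
    within_subject_correlation: float = 0.5
    axial_noise_sd: float = 2.0
    undulation_amplitude_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if not (0.0 <= self.within_subject_correlation <= 1.0):
            raise ValueError("within_subject_correlation must lie in [0, 1]")
        if any(n < 1 for n in self.grid):
            raise ValueError("grid dimensions must be >= 1")
        total = sum(_LAYER_THICKNESS_UM.values())
        if not (0.0 <= self.foveal_pit_depth < total):
            raise ValueError(
                f"foveal_pit_depth must lie in [0, {total}) µm to keep "
                "boundaries ordered"
            )


@dataclass
class LayerSurfaces:
    """Ordered boundary depth maps (µm) over the en-face grid.

    ``depths`` has shape ``(len(BOUNDARIES), ny, nx)`` and is strictly
    increasing along its first axis wherever layers have positive thickness.
    """

    depths: np.ndarray
    names: tuple[str, ...] = BOUNDARIES

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 3 or self.depths.shape[0] != len(self.names):
            raise ValueError("depths must have shape (n_boundaries, ny, nx)")

    def boundary(self, name: str) -> np.ndarray:
        return self.depths[self.names.index(name)]

    def layer_interfaces(self, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """Upper and lower boundary depth maps for one of the six layers."""
        i = LAYERS.index(layer)
        return self.depths[i], self.depths[i + 1]

    def check_ordering(self) -> None:
        if np.any(np.diff(self.depths, axis=0) < 0):
            raise ValueError("boundary surfaces cross")

    def mirrored(self) -> "LayerSurfaces":
        return LayerSurfaces(self.depths[:, :, ::-1].copy(), self.names)


@dataclass
class OCTVolume:
    """One eye's intensity volume with voxel-scale metadata."""

    intensity: np.ndarray  # (ny, nx, nz)
    voxel_scale: tuple[float, float, float]  # µm per voxel (x, y, z)
    laterality: str  # "left" | "right"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (ny, nx, nz)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")


@dataclass
class EyeRecord:
    subject_id: str
    laterality: str
    class_label: str
    volume: OCTVolume
    surfaces: LayerSurfaces
    #: Noise-free per-layer texture fields, mainly for tests/diagnostics.
    texture_fields: dict[str, np.ndarray] | None = None


def _subject_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent named substream: adding subjects never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_layer_texture(
    params: LayerTextureParams,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary correlated Gaussian texture field for one layer.

    White Gaussian noise is smoothed with an anisotropic Gaussian kernel of
    widths ``(correlation_length_y, correlation_length_x)`` pixels, re-scaled
    to unit marginal variance, then scaled by ``contrast_gain * noise_sd``
    and shifted by ``base_intensity``.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError("shape must be positive")
    field_ = rng.standard_normal((ny, nx))
    if params.noise_sd == 0:
        return np.full((ny, nx), params.base_intensity)
    field_ = gaussian_filter(
        field_, sigma=(params.correlation_length_y, params.correlation_length_x),
        mode="reflect",
    )
    sd = field_.std()
    if sd > 0:
        field_ = (field_ - field_.mean()) / sd
    return params.base_intensity + params.contrast_gain * params.noise_sd * field_


def _unit_texture(
    params: LayerTextureParams, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance correlated field (pre scale/shift)."""
    probe = replace(params, base_intensity=0.0, noise_sd=1.0, contrast_gain=1.0)
    return generate_layer_texture(probe, shape, rng)


def generate_surfaces(
    config: CohortConfig, rng: np.random.Generator
) -> LayerSurfaces:
    """Smooth ordered boundary surfaces with a central foveal depression.

    Each boundary is displaced downward by the pit profile weighted by the
    fraction of retinal tissue below it, so the pit attenuates inner → outer
    and the full ILM→RPE thickness at the pit centre is reduced by exactly
    ``foveal_pit_depth``.  A gentle smooth undulation common to all
    boundaries models scan tilt without changing any thickness.
    """
    nx, ny, _ = config.grid
    sx, sy, _ = config.voxel_scale
    xs = (np.arange(nx) - (nx - 1) / 2.0) * sx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * sy
    r2 = ys[:, None] ** 2 + xs[None, :] ** 2
    pit = config.foveal_pit_depth * np.exp(-r2 / (2.0 * config.pit_radius_um**2))

    thick = [_LAYER_THICKNESS_UM[k] for k in (*LAYERS, "PR")]
    total = sum(thick)
    cum = np.concatenate([[0.0], np.cumsum(thick)])  # depth of each boundary

    if config.undulation_amplitude_um > 0:
        tilt = gaussian_filter(
            rng.standard_normal((ny, nx)), sigma=(max(ny / 8, 1), max(nx / 8, 1)),
            mode="reflect",
        )
        sd = tilt.std()
        tilt = (
            config.undulation_amplitude_um * (tilt - tilt.mean()) / sd
            if sd > 0
            else np.zeros((ny, nx))
        )
    else:
        tilt = np.zeros((ny, nx))

    depths = np.empty((len(BOUNDARIES), ny, nx))
    for i, c in enumerate(cum):
        weight = (total - c) / total  # 1 at ILM, 0 at RPE top
        depths[i] = _ILM_BASE_DEPTH_UM + c + weight * pit + tilt
    surf = LayerSurfaces(depths)
    surf.check_ordering()
    return surf


def _build_volume(
    config: CohortConfig,
    surfaces: LayerSurfaces,
    textures: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint each layer's texture into the voxels between its boundaries."""
    nx, ny, nz = config.grid
    sz = config.voxel_scale[2]
    zb = np.rint(surfaces.depths / sz).astype(np.int64)  # (8, ny, nx)
    z = np.arange(nz)
    # region r = number of boundaries at or above voxel z:
    # 0 vitreous, 1..6 the six layers, 7 photoreceptor complex, 8 below RPE.
    region = (z[None, None, :] >= zb[:, :, :, None]).sum(axis=0)
    vol = np.full((ny, nx, nz), _VITREOUS_GREY)
    for i, layer in enumerate(LAYERS):
        vol = np.where(region == i + 1, textures[layer][:, :, None], vol)
    vol = np.where(region == 7, _PR_GREY, vol)
    vol = np.where(region == 8, _BELOW_RPE_GREY, vol)
    if config.axial_noise_sd > 0:
        vol = vol + rng.normal(0.0, config.axial_noise_sd, size=vol.shape)
    return vol


def generate_eye(
    config: CohortConfig,
    params: ClassTextureParams,
    subject_index: int,
    laterality: str,
    subject_id: str,
) -> EyeRecord:
    """Generate one eye deterministically from the cohort seed.

    The texture field of each layer is a variance-preserving mixture of a
    subject-shared field and an eye-specific field,
    ``sqrt(w)*shared + sqrt(1-w)*own`` with ``w = within_subject_correlation``,
    so the inter-eye field correlation equals ``w`` exactly and ``w = 1``
    makes the two eyes' texture identical.  Left eyes are stored mirrored
    along x (columns run nasal → temporal).
    """
    nx, ny, _ = config.grid
    eye_idx = 0 if laterality == "right" else 1
    ci = CLASSES.index(params.class_label)
    w = config.within_subject_correlation

    surf_rng = _subject_rng(config.seed, ci, subject_index, 0, 0)
    surfaces = generate_surfaces(config, surf_rng)

    textures: dict[str, np.ndarray] = {}
    for li, layer in enumerate(LAYERS):
        lp = params.layers[layer]
        shared_rng = _subject_rng(config.seed, ci, subject_index, 1, li)
        own_rng = _subject_rng(config.seed, ci, subject_index, 2 + eye_idx, li)
        shared = _unit_texture(lp, (ny, nx), shared_rng)
        own = _unit_texture(lp, (ny, nx), own_rng)
        unit = np.sqrt(w) * shared + np.sqrt(1.0 - w) * own
        textures[layer] = (
            lp.base_intensity + lp.contrast_gain * lp.noise_sd * unit
        )

    noise_rng = _subject_rng(config.seed, ci, subject_index, 4 + eye_idx, 0)
    vol = _build_volume(config, surfaces, textures, noise_rng)

    if laterality == "left":
        vol = vol[:, ::-1, :].copy()
        surfaces = surfaces.mirrored()
        textures = {k: v[:, ::-1].copy() for k, v in textures.items()}

    volume = OCTVolume(vol, config.voxel_scale, laterality)
    return EyeRecord(subject_id, laterality, params.class_label, volume,
                     surfaces, textures)


def iter_cohort(config, params_by_class):
    """Yield EyeRecords one at a time (volumes are large; avoid holding all)."""
    for class_label in CLASSES:
        params = params_by_class[class_label]
        if params.class_label != class_label:
            raise ValueError("params_by_class key/label mismatch")
        for s in range(config.n_subjects_per_class):
            sid = f"{class_label}{s:03d}"
            for lat in ("right", "left"):
                yield generate_eye(config, params, s, lat, sid)


def generate_cohort(
    config: CohortConfig,
    params_by_class: dict[str, ClassTextureParams],
) -> list[EyeRecord]:
    """Materialise the full cohort: two mirrored eyes per subject, balanced
    classes, fully reproducible from ``config.seed``."""
    return list(iter_cohort(config, params_by_class))


def example_class_params(effect_scale: float = 1.0) -> dict[str, ClassTextureParams]:
    """Reference class-conditional texture parameter sets.

    ``effect_scale = 1`` is the well-separated ("strong effect") cohort used
    for end-to-end checks; ``effect_scale = 0`` collapses all three classes
    onto the HC parameters (the null cohort).  The disease effects are
    illustrative knobs — coarser, higher-contrast texture for AD and
    elongated, lower-contrast texture for PD — not claims about pathology.
    """

    def lerp(a: float, b: float) -> float:
        return a + effect_scale * (b - a)

    hc = LayerTextureParams(
        base_intensity=100.0, noise_sd=12.0,
        correlation_length_x=8.0, correlation_length_y=2.0, contrast_gain=1.0,
    )
    ad = LayerTextureParams(
        base_intensity=100.0, noise_sd=12.0,
        correlation_length_x=lerp(8.0, 16.0),
        correlation_length_y=lerp(2.0, 4.0),
        contrast_gain=lerp(1.0, 1.35),
    )
    pd_ = LayerTextureParams(
        base_intensity=100.0, noise_sd=lerp(12.0, 10.0),
        correlation_length_x=lerp(8.0, 24.0),
        correlation_length_y=2.0,
        contrast_gain=lerp(1.0, 0.8),
    )
    return {
        "HC": ClassTextureParams("HC", {lyr: hc for lyr in LAYERS}),
        "AD": ClassTextureParams("AD", {lyr: ad for lyr in LAYERS}),
        "PD": ClassTextureParams("PD", {lyr: pd_ for lyr in LAYERS}),
    }
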