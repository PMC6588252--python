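"""Texture features of mean-value-fundus images.

Each retinal layer's MVF image yields an 86-dimensional feature vector:

* 80 *local* features: the image is resampled to 128x128, quantised to 16
  grey levels, cropped centrally to 126x126 and split into 7x7 blocks of
  18x18 px.  For every block, 20 co-occurrence (GLCM) metrics are computed
  at unit distance in four directions (0°, 45°, 90°, 135°) and the supremum
  over directions is kept.  Block metrics are averaged per macular quadrant
  over the 3x3 corner blocks, leaving out the central row and column that
  pass through the fovea — 4 quadrants x 20 metrics.
* 6 *global* features: the variances of the complex-coefficient magnitudes
  of the six directionally selective level-1 DTCWT subbands (±15°, ±45°,
  ±75°).

All operations assume right-eye orientation (columns temporal → nasal);
images must be laterality-normalised first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix
from skimage.measure import block_reduce
from skimage.transform import resize

from ._dtcwt import SUBBAND_ORDER, dtcwt_level1
from .fundus import MVFImage

WORKING_SIZE = 128
CROPPED_SIZE = 126  # 7 x 18 px blocks
N_BLOCKS = 7
BLOCK_PX = CROPPED_SIZE // N_BLOCKS
N_LEVELS = 16

DIRECTIONS = (0, 45, 90, 135)
#: Pixel offsets (drow, dcol) for each direction; 45° is the up-right
#: diagonal.  Under GLCM symmetry the opposite offset is equivalent.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (1, 1)}
#: skimage's angle parametrisation labels the up-right diagonal 3π/4.
_SKIMAGE_ANGLE = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}

METRIC_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

QUADRANTS = (
    "superior_temporal",
    "superior_nasal",
    "inferior_temporal",
    "inferior_nasal",
)
#: Block-grid slices per quadrant (rows superior → inferior, cols temporal
#: → nasal); the centre row/column (index 3) is excluded.
QUADRANT_BLOCKS = {
    "superior_temporal": (slice(0, 3), slice(0, 3)),
    "superior_nasal": (slice(0, 3), slice(4, 7)),
    "inferior_temporal": (slice(4, 7), slice(0, 3)),
    "inferior_nasal": (slice(4, 7), slice(4, 7)),
}


@dataclass
class QuantizedImage:
    """16-level working image derived from one MVF image."""

    levels: np.ndarray  # (128, 128) uint8 in 0..15
    layer: str

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.shape != (WORKING_SIZE, WORKING_SIZE):
            raise ValueError(f"levels must be {WORKING_SIZE}x{WORKING_SIZE}")
        if self.levels.min() < 0 or self.levels.max() >= N_LEVELS:
            raise ValueError("levels outside 0..15")

    def working(self) -> np.ndarray:
        """Central 126x126 crop that the 7x7 block grid tiles exactly."""
        return self.levels[1 : 1 + CROPPED_SIZE, 1 : 1 + CROPPED_SIZE]


@dataclass
class BlockGrid:
    """Direction-supremum GLCM metrics for every block of the 7x7 grid."""

    values: np.ndarray  # (7, 7, 20)
    metric_names: tuple[str, ...] = METRIC_NAMES

    def metric(self, name: str) -> np.ndarray:
        return self.values[:, :, self.metric_names.index(name)]


@dataclass
class FeatureVector:
    """86 named texture features for one (eye, layer) pair."""

    values: np.ndarray
    names: tuple[str, ...]
    origins: tuple[str, ...]  # quadrant name or "global"
    layer: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.values) == len(self.names) == len(self.origins) == 86):
            raise ValueError("feature vector must have exactly 86 entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def feature_names() -> tuple[str, ...]:
    """Stable 86-name order: 80 local (quadrant x metric), then 6 global."""
    local = tuple(
        f"glcm_{quad}_{metric}" for quad in QUADRANTS for metric in METRIC_NAMES
    )
    global_ = tuple(f"dtcwt_var_{band}" for band in SUBBAND_ORDER)
    return local + global_


def feature_origins() -> tuple[str, ...]:
    local = tuple(quad for quad in QUADRANTS for _ in METRIC_NAMES)
    return local + ("global",) * len(SUBBAND_ORDER)


def _downsample(values: np.ndarray, size: int = WORKING_SIZE) -> np.ndarray:
    """Resample an en-face image to size x size.

    Integer reduction factors use exact local-mean pooling; anything else
    (including grids smaller than the target) goes through an anti-aliased
    resampling with the same local-averaging intent.
    """
    ny, nx = values.shape
    if ny % size == 0 and nx % size == 0:
        return block_reduce(values, (ny // size, nx // size), np.mean)
    return resize(values, (size, size), anti_aliasing=ny > size or nx > size,
                  preserve_range=True, mode="reflect")


def downsample_quantize(image: MVFImage) -> QuantizedImage:
    """Resample to 128x128 and quantise the image's own intensity range into
    16 equal-width grey-level bins (a constant image maps to level 0)."""
    if not image.normalised:
        raise ValueError("image must be laterality-normalised first")
    if not np.all(np.isfinite(image.values)):
        raise ValueError("non-finite values in MVF image")
    small = _downsample(image.values)
    lo, hi = small.min(), small.max()
    if hi == lo:
        q = np.zeros_like(small, dtype=np.uint8)
    else:
        q = np.clip(
            ((small - lo) / (hi - lo) * N_LEVELS).astype(np.int64), 0, N_LEVELS - 1
        ).astype(np.uint8)
    return QuantizedImage(q, image.layer)


def glcm(block: np.ndarray, direction: int, levels: int = N_LEVELS) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix at unit distance.

    ``direction`` is one of 0, 45, 90, 135 degrees (45° pairs each pixel
    with its upper-right neighbour).
    """
    block = np.asarray(block)
    if direction not in DIRECTION_OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    dr, dc = DIRECTION_OFFSETS[direction]
    if (abs(dr) and block.shape[0] < 2) or (abs(dc) and block.shape[1] < 2):
        raise ValueError("block smaller than 2 px in the offset direction")
    if block.min() < 0 or block.max() >= levels:
        raise ValueError(f"block values must lie in 0..{levels - 1}")
    m = graycomatrix(
        block.astype(np.uint8), [1], [_SKIMAGE_ANGLE[direction]],
        levels=levels, symmetric=True, normed=True,
    )
    return m[:, :, 0, 0]


def _glcm_stack(block: np.ndarray, levels: int = N_LEVELS) -> np.ndarray:
    """All four directional GLCMs of one block, shape (4, levels, levels)."""
    angles = [_SKIMAGE_ANGLE[d] for d in DIRECTIONS]
    m = graycomatrix(block.astype(np.uint8), [1], angles, levels=levels,
                     symmetric=True, normed=True)
    return np.moveaxis(m[:, :, 0, :], -1, 0)


def glcm_metrics_stack(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 20 GLCM metrics, vectorised over leading axes of ``P``.

    ``P`` has shape ``(..., L, L)`` and must be normalised (entries of each
    matrix sum to 1).  Entropies are in bits; the internal entropies of the
    two information measures of correlation (IMC1/IMC2) use natural logs as
    in their classical definition.  Degenerate marginals (zero variance)
    yield correlation 0 and IMC1 0.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[-1]
    sums = P.sum(axis=(-2, -1))
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalised (entries sum to 1)")
    i = np.arange(L)[:, None] * np.ones((1, L))
    j = i.T
    px = P.sum(axis=-1)  # (..., L)
    py = P.sum(axis=-2)
    mu_x = (px * np.arange(L)).sum(axis=-1)
    mu_y = (py * np.arange(L)).sum(axis=-1)
    sig_x = np.sqrt((px * (np.arange(L) - mu_x[..., None]) ** 2).sum(axis=-1))
    sig_y = np.sqrt((py * (np.arange(L) - mu_y[..., None]) ** 2).sum(axis=-1))

    def plog2p(p):
        return np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0)

    def plnp(p):
        return np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)

    out: dict[str, np.ndarray] = {}
    diff2 = (i - j) ** 2
    out["autocorrelation"] = (P * i * j).sum(axis=(-2, -1))
    out["contrast"] = (P * diff2).sum(axis=(-2, -1))
    denom = sig_x * sig_y
    corr_num = out["autocorrelation"] - mu_x * mu_y
    out["correlation"] = np.where(denom > 0, corr_num / np.where(denom > 0, denom, 1.0), 0.0)
    dev = i + j - mu_x[..., None, None] - mu_y[..., None, None]
    out["cluster_prominence"] = (P * dev**4).sum(axis=(-2, -1))
    out["cluster_shade"] = (P * dev**3).sum(axis=(-2, -1))
    out["dissimilarity"] = (P * np.abs(i - j)).sum(axis=(-2, -1))
    out["energy"] = (P**2).sum(axis=(-2, -1))
    out["entropy"] = -plog2p(P).sum(axis=(-2, -1))
    out["homogeneity"] = (P / (1.0 + diff2)).sum(axis=(-2, -1))
    out["maximum_probability"] = P.max(axis=(-2, -1))
    out["variance"] = (P * (i - mu_x[..., None, None]) ** 2).sum(axis=(-2, -1))

    # marginal distributions of i+j and |i-j|
    ks = np.arange(2 * L - 1)
    p_sum = np.stack(
        [P[..., i + j == k].sum(axis=-1) for k in ks], axis=-1
    )
    kd = np.arange(L)
    p_diff = np.stack(
        [P[..., np.abs(i - j) == k].sum(axis=-1) for k in kd], axis=-1
    )
    sa = (p_sum * ks).sum(axis=-1)
    out["sum_average"] = sa
    out["sum_variance"] = (p_sum * (ks - sa[..., None]) ** 2).sum(axis=-1)
    out["sum_entropy"] = -plog2p(p_sum).sum(axis=-1)
    da = (p_diff * kd).sum(axis=-1)
    out["difference_variance"] = (p_diff * (kd - da[..., None]) ** 2).sum(axis=-1)
    out["difference_entropy"] = -plog2p(p_diff).sum(axis=-1)

    hx = -plnp(px).sum(axis=-1)
    hy = -plnp(py).sum(axis=-1)
    hxy = -plnp(P).sum(axis=(-2, -1))
    pxpy = px[..., :, None] * py[..., None, :]
    lg = np.where(pxpy > 0, np.log(np.maximum(pxpy, 1e-300)), 0.0)
    hxy1 = -(P * lg).sum(axis=(-2, -1))
    hxy2 = -(pxpy * lg).sum(axis=(-2, -1))
    hmax = np.maximum(hx, hy)
    out["imc1"] = np.where(hmax > 0, (hxy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    out["imc2"] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    out["inverse_difference_normalized"] = (
        P / (1.0 + np.abs(i - j) / L)
    ).sum(axis=(-2, -1))
    out["inverse_difference_moment_normalized"] = (
        P / (1.0 + diff2 / L**2)
    ).sum(axis=(-2, -1))
    return out


def glcm_metrics(matrix: np.ndarray) -> dict[str, float]:
    """The 20 named scalar metrics of one normalised GLCM."""
    stack = glcm_metrics_stack(np.asarray(matrix)[None])
    return {name: float(stack[name][0]) for name in METRIC_NAMES}


def block_features(qimg: QuantizedImage) -> BlockGrid:
    """Per-block direction-supremum GLCM metrics over the 7x7 grid."""
    work = qimg.working()
    mats = np.empty((N_BLOCKS * N_BLOCKS, len(DIRECTIONS), N_LEVELS, N_LEVELS))
    for bi in range(N_BLOCKS):
        for bj in range(N_BLOCKS):
            blk = work[bi * BLOCK_PX : (bi + 1) * BLOCK_PX,
                       bj * BLOCK_PX : (bj + 1) * BLOCK_PX]
            mats[bi * N_BLOCKS + bj] = _glcm_stack(blk)
    metrics = glcm_metrics_stack(mats)  # each (49, 4)
    values = np.stack(
        [metrics[name].max(axis=-1) for name in METRIC_NAMES], axis=-1
    ).reshape(N_BLOCKS, N_BLOCKS, len(METRIC_NAMES))
    return BlockGrid(values)


def aggregate_quadrants(grid: BlockGrid) -> dict[str, float]:
    """80 local features: quadrant means over the 3x3 corner blocks."""
    out: dict[str, float] = {}
    for quad in QUADRANTS:
        rs, cs = QUADRANT_BLOCKS[quad]
        sub = grid.values[rs, cs, :]  # (3, 3, 20)
        means = sub.mean(axis=(0, 1))
        for m, name in enumerate(grid.metric_names):
            out[f"glcm_{quad}_{name}"] = float(means[m])
    return out


def dtcwt_features(image: MVFImage | np.ndarray) -> dict[str, float]:
    """Variance of complex-coefficient magnitudes of the six level-1
    directional subbands (population 1/N normalisation).

    Detail subbands have zero response to constants, so the features are
    invariant to additive intensity offsets.  Odd image dimensions are
    edge-padded to even.
    """
    values = image.values if isinstance(image, MVFImage) else np.asarray(image, float)
    if isinstance(image, MVFImage) and not image.normalised:
        raise ValueError("image must be laterality-normalised first")
    ny, nx = values.shape
    pad = ((0, ny % 2), (0, nx % 2))
    if any(p[1] for p in pad):
        values = np.pad(values, pad, mode="edge")
    bands = dtcwt_level1(values)
    return {
        f"dtcwt_var_{name}": float(np.var(np.abs(bands[name])))
        for name in SUBBAND_ORDER
    }


def extract_features(image: MVFImage) -> FeatureVector:
    """Full 86-feature vector of one laterality-normalised MVF image.

    Both feature families are computed from the common 128x128 isotropic
    resampling of the image: the GLCM path additionally quantises to 16
    levels, the DTCWT path uses the un-quantised resampled intensities.
    """
    if not image.normalised:
        raise ValueError("image must be laterality-normalised first")
    small = _downsample(image.values)
    qimg = downsample_quantize(image)
    local = aggregate_quadrants(block_features(qimg))
    global_ = dtcwt_features(small)
    names = feature_names()
    values = np.array([{**local, **global_}[n] for n in names])
    return FeatureVector(values, names, feature_origins(), image.layer)


def quadrant_layer_thickness(
    thickness_map: np.ndarray, quadrant: str
) -> float:
    """Mean layer thickness over the same 3x3-block footprint a texture
    quadrant aggregates, so feature and thickness share spatial support."""
    small = _downsample(np.asarray(thickness_map, dtype=float))
    work = small[1 : 1 + CROPPED_SIZE, 1 : 1 + CROPPED_SIZE]
    rs, cs = QUADRANT_BLOCKS[quadrant]
    rpix = slice(rs.start * BLOCK_PX, rs.stop * BLOCK_PX)
    cpix = slice(cs.start * BLOCK_PX, cs.stop * BLOCK_PX)
    return float(work[rpix, cpix].mean())
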