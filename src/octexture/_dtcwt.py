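"""Level-1 dual-tree complex wavelet transform (2-D).

Only the first decomposition level is needed here, where the dual tree can
be realised with a single odd-length symmetric biorthogonal filter pair:
the full-rate filtered image is split into its four sample-phase quadrants
(the two trees are the even/odd phases on each axis) and recombined into
two approximately analytic complex subbands per highpass orientation,
giving the six directionally selective subbands at roughly ±15°, ±45° and
±75°.

The filter pair is the CDF 9/7 (Antonini) biorthogonal pair taken from
PyWavelets (``bior4.4``), a standard level-1 choice for this transform.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d

_WAVELET = pywt.Wavelet("bior4.4")
#: 9-tap symmetric lowpass / 7-tap symmetric highpass analysis filters.
H0 = np.trim_zeros(np.asarray(_WAVELET.dec_lo))
H1 = np.trim_zeros(np.asarray(_WAVELET.dec_hi))

#: Subband order used throughout: degrees measured from the x-axis with y
#: pointing down; −15° ≡ 165° etc.
SUBBAND_ORDER = ("p15", "p45", "p75", "m75", "m45", "m15")


def _colfilter(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-phase filtering along axis 0 with symmetric extension."""
    return correlate1d(x, h, axis=0, mode="reflect")


def _rowfilter(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    return correlate1d(x, h, axis=1, mode="reflect")


def _q2c(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadrant samples → two complex subbands of opposite orientation.

    The four sample phases are the four tree combinations; the complex
    combinations (a−d) + j(b+c) and (a+d) + j(b−c) select the two
    frequency-plane quadrants (±θ orientations).
    """
    a = y[0::2, 0::2]
    b = y[0::2, 1::2]
    c = y[1::2, 0::2]
    d = y[1::2, 1::2]
    s = np.sqrt(0.5)
    return ((a - d) + 1j * (b + c)) * s, ((a + d) + 1j * (b - c)) * s


def dtcwt_level1(image: np.ndarray) -> dict[str, np.ndarray]:
    """One-level DTCWT: six complex directional subbands of a 2-D image.

    The image must have even dimensions and be at least as long as the
    filters on both axes.  Returns subbands keyed by :data:`SUBBAND_ORDER`.
    """
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if min(ny, nx) < len(H0):
        raise ValueError("image too small for one decomposition level")
    if ny % 2 or nx % 2:
        raise ValueError("image dimensions must be even (pad first)")
    lo = _colfilter(image, H0)
    hi = _colfilter(image, H1)
    p15, m15 = _q2c(_rowfilter(hi, H0))  # y-highpass: near-horizontal detail
    p75, m75 = _q2c(_rowfilter(lo, H1))  # x-highpass: near-vertical detail
    p45, m45 = _q2c(_rowfilter(hi, H1))  # diagonal detail
    return {"p15": p15, "p45": p45, "p75": p75,
            "m75": m75, "m45": m45, "m15": m15}
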