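"""Canonical hemodynamic response function.

Double-gamma impulse response: a positive gamma peaking at ``peak_delay``
seconds minus an undershoot gamma peaking at ``undershoot_delay`` seconds,
scaled by ``1/ratio``.  Gamma shapes are ``delay/dispersion + 1`` so the
mode of each lobe sits exactly at its stated delay.  The kernel has finite
support [0, length) and is normalised to unit peak, so a unit-amplitude
neural event produces a unit-peak BOLD response.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def canonical_hrf(
    tr: float,
    oversampling: int = 16,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a grid of ``tr/oversampling``
    seconds. ``h(0) = 0`` and the kernel is zero beyond ``length`` seconds."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, length, dt)
    peak = stats.gamma.pdf(t, a=peak_delay / peak_dispersion + 1, scale=peak_dispersion)
    under = stats.gamma.pdf(
        t, a=undershoot_delay / undershoot_dispersion + 1, scale=undershoot_dispersion
    )
    h = peak - under / ratio
    return h / h.max()
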