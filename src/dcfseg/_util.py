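"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_up"]


def round_half_up(x):
    """Round to the nearest integer with halves going up (0.5 -> 1).

    Used project-wide wherever a real-valued coordinate or intensity is
    rasterized, so that every stage shares one rounding convention.
    Accepts scalars or arrays; returns int64 scalars/arrays.
    """
    arr = np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)
    if np.isscalar(x) or np.ndim(x) == 0:
        return int(arr)
    return arr
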