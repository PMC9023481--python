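"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_even"]


def round_half_even(x: float) -> int:
    """Seconds-to-samples rounding used everywhere in the package.

    One shared rule (banker's rounding, matching IEEE round-to-nearest-even)
    avoids off-by-one drift between window formulas computed in different
    modules.
    """
    return int(np.rint(x))
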