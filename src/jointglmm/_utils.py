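"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of printed clinical tables).

    numpy's ``round`` rounds half to even, which disagrees with how
    percentages like 753/1408 = 53.48 -> 53.5 are typically printed.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def check_rate(rate: float, name: str = "rate") -> float:
    rate = float(rate)
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {rate}")
    return rate
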