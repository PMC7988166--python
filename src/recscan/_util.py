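"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention used for printed tables).

    numpy's default is banker's rounding; printed genotype tables in this
    field round 0.5 up in magnitude, so 2.5 -> 3 and -2.5 -> -3.
    """
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if decimals <= 0:
        out = out.astype(int) if out.ndim else int(out)
        return out
    return float(out) if arr.ndim == 0 else out


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
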