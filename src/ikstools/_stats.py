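"""Mean ± standard-error summaries used across the pipeline."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["mean_se"]


def mean_se(values: Sequence[float]) -> tuple[float, float | None, int]:
    """(mean, SE, n).  SE = sample SD / sqrt(n); ``None`` when n = 1."""
    arr = np.asarray([v for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError("mean_se of an empty list")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None, 1
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, se, int(arr.size)
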