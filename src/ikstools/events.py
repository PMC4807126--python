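"""Run-length utilities shared by the gating simulator and the idealizer.

Both sides speak the same representation: a per-sample integer array of
ladder level indices (0 = closed), and an event list of
``(level_index, start_s, duration_s)`` tuples tiling the analyzed window.
Keeping discretization and short-event merging in one place is what makes
the idealizer exactly comparable with the simulator's own event log.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["runs", "merge_short_runs", "events_from_levels", "levels_from_events"]


def runs(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RLE of an integer array: (values, start_indices, lengths)."""
    levels = np.asarray(levels)
    if levels.size == 0:
        return np.array([], int), np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [levels.size]]))
    return levels[starts], starts, lengths


def merge_short_runs(levels: np.ndarray, amplitudes: Sequence[float],
                     min_samples: int) -> np.ndarray:
    """Absorb runs shorter than ``min_samples`` into a flanking run.

    The shortest run is processed first (leftmost on ties) and is merged
    into the neighbour whose ladder amplitude is closer to its own; the
    result has no run shorter than ``min_samples`` unless only one run
    remains.  Total sample count is conserved.
    """
    amplitudes = np.asarray(amplitudes, float)
    vals, _, lens = runs(np.asarray(levels))
    vals, lens = list(vals), list(lens)
    while len(vals) > 1:
        shortest = int(np.argmin(lens))
        if lens[shortest] >= min_samples:
            break
        if shortest == 0:
            target = 1
        elif shortest == len(vals) - 1:
            target = shortest - 1
        else:
            d_prev = abs(amplitudes[vals[shortest - 1]] - amplitudes[vals[shortest]])
            d_next = abs(amplitudes[vals[shortest + 1]] - amplitudes[vals[shortest]])
            target = shortest - 1 if d_prev <= d_next else shortest + 1
        lens[target] += lens[shortest]
        del vals[shortest], lens[shortest]
        # coalesce newly adjacent equal levels
        i = max(0, (target if target < shortest else target - 1) - 1)
        while i + 1 < len(vals):
            if vals[i] == vals[i + 1]:
                lens[i] += lens[i + 1]
                del vals[i + 1], lens[i + 1]
            else:
                i += 1
    return np.repeat(np.asarray(vals, int), np.asarray(lens, int))


def events_from_levels(levels: np.ndarray, fs: float,
                       t0_s: float = 0.0) -> list[tuple[int, float, float]]:
    """Event tuples ``(level, start_s, duration_s)`` from per-sample levels."""
    vals, starts, lengths = runs(levels)
    return [(int(v), t0_s + s / fs, n / fs)
            for v, s, n in zip(vals, starts, lengths)]


def levels_from_events(events: Sequence[tuple[int, float, float]], fs: float,
                       n_samples: int, t0_s: float = 0.0) -> np.ndarray:
    """Sample an event list onto the grid (sample i covers [i/fs, (i+1)/fs))."""
    out = np.zeros(n_samples, dtype=int)
    for level, start, dur in events:
        a = int(np.floor((start - t0_s) * fs + 0.5e-9))
        b = int(np.floor((start + dur - t0_s) * fs + 0.5e-9))
        a, b = max(a, 0), min(b, n_samples)
        if b > a:
            out[a:b] = level
    return out
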