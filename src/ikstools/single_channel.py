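"""Single-channel idealization, amplitude histograms and dwell analysis.

Sweeps are idealized over a subconductance ladder by nearest-amplitude
classification: boundaries are the midpoints of adjacent ladder levels
(the six printed sublevels plus the closed level), and runs shorter than
the resolvable dwell (half the filter rise time by default) are absorbed
into the flanking level with the closer amplitude.  All-points amplitude
histograms over the test step, with Gaussian mixture peak fits anchored at
the ladder, locate the dominant open level; dwell summaries, per-sweep
first latencies and reversal-anchored slope-conductance fits reproduce the
published single-channel parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import mean_se
from .events import events_from_levels, merge_short_runs
from .trace_io import AnalysisConfig, ConfigurationError, SweepSet, get_logger

__all__ = [
    "IdealizedTrace",
    "DwellSummary",
    "AmplitudeHistogram",
    "GaussianPeaks",
    "SlopeFit",
    "NoOpenPeakError",
    "detect_active_sweeps",
    "build_allpoints_histogram",
    "fit_histogram_peaks",
    "idealize_trace",
    "idealize_sweeps",
    "summarize_dwells",
    "first_latency",
    "estimate_slope_conductance",
]

log = get_logger("single_channel")


class NoOpenPeakError(ValueError):
    """The histogram has no open-level Gaussian component of usable weight."""


@dataclass
class IdealizedTrace:
    """Event sequence of one sweep over the ladder, timed from step onset.

    Events ``(level_index, start_s, duration_s)`` tile the analyzed step
    contiguously and consecutive events differ in level.
    """

    sweep_id: int
    events: list[tuple[int, float, float]]
    duration_s: float

    def __post_init__(self) -> None:
        t = 0.0
        prev = None
        for level, start, dur in self.events:
            if abs(start - t) > 1e-9:
                raise ValueError("events must tile the step contiguously")
            if prev is not None and level == prev:
                raise ValueError("consecutive events must differ in level")
            t = start + dur
            prev = level
        if self.events and abs(t - self.duration_s) > 1e-9:
            raise ValueError("events must span the full analyzed step")

    @property
    def is_blank(self) -> bool:
        return all(level == 0 for level, _, _ in self.events)


def first_latency(trace: IdealizedTrace) -> float | None:
    """Start time of the first open event from depolarization onset;
    ``None`` for blank sweeps (flagged, excluded from means)."""
    for level, start, _ in trace.events:
        if level > 0:
            return start
    return None


# --------------------------------------------------------------------------
# idealization


def _min_samples(cfg: AnalysisConfig, fs: float) -> int:
    n = int(round(cfg.min_dwell_s * fs))
    if n < 2:
        raise ConfigurationError(
            f"min_dwell_s = {cfg.min_dwell_s} s is shorter than 2 samples "
            f"at {fs} Hz")
    return n


def idealize_trace(samples: np.ndarray, fs: float, cfg: AnalysisConfig, *,
                   sweep_id: int = 0, voltage_mV: float = 60.0) -> IdealizedTrace:
    """Idealize one (already filtered) test-step segment.

    Each sample is classified to the nearest ladder amplitude (ladder
    scaled to ``voltage_mV`` along the driving force); sub-resolution runs
    are merged into the flanking level with closer amplitude.
    """
    samples = np.asarray(samples, float)
    ladder = cfg.ladder_at(voltage_mV)
    thresholds = (ladder[:-1] + ladder[1:]) / 2.0
    levels = np.searchsorted(thresholds, samples)
    levels = merge_short_runs(levels, ladder, _min_samples(cfg, fs))
    return IdealizedTrace(sweep_id=sweep_id,
                          events=events_from_levels(levels, fs),
                          duration_s=samples.size / fs)


def idealize_sweeps(s: SweepSet, cfg: AnalysisConfig,
                    ids: Iterable[int] | None = None) -> list[IdealizedTrace]:
    """Idealize the test step of the selected sweeps of a set."""
    sl = s.test_step_slice()
    ids = range(s.n_sweeps) if ids is None else list(ids)
    return [idealize_trace(s.sweeps[i, sl], s.sampling_rate_Hz, cfg,
                           sweep_id=i, voltage_mV=s.test_voltage(i))
            for i in ids]


def detect_active_sweeps(
    s: SweepSet, cfg: AnalysisConfig,
) -> tuple[list[int], list[int]]:
    """Partition sweep ids into (active, blank).

    A sweep is active iff the test step holds at least one excursion above
    the lowest open-level boundary sustained for ``min_dwell_s``.
    """
    sl = s.test_step_slice()
    min_n = _min_samples(cfg, s.sampling_rate_Hz)
    active, blank = [], []
    for i in range(s.n_sweeps):
        thr = cfg.ladder_at(s.test_voltage(i))[1] / 2.0
        above = s.sweeps[i, sl] > thr
        # longest run of True
        padded = np.concatenate([[0], above.astype(int), [0]])
        d = np.diff(padded)
        run_lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        (active if run_lengths.size and run_lengths.max() >= min_n
         else blank).append(i)
    return active, blank


# --------------------------------------------------------------------------
# all-points histograms and Gaussian peaks


@dataclass
class AmplitudeHistogram:
    bin_edges_pA: np.ndarray
    counts: np.ndarray
    included_sweep_ids: tuple[int, ...]
    active_only: bool

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges_pA) - 1:
            raise ValueError("counts length must equal edges length - 1")

    @property
    def centers_pA(self) -> np.ndarray:
        return (self.bin_edges_pA[:-1] + self.bin_edges_pA[1:]) / 2.0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_allpoints_histogram(s: SweepSet, ids: Sequence[int],
                              cfg: AnalysisConfig, *,
                              active_only: bool = True) -> AmplitudeHistogram:
    """All-points amplitude histogram over the test step of ``ids``."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty sweep id set")
    sl = s.test_step_slice()
    data = s.sweeps[ids, sl].ravel()
    b = cfg.histogram_bin_pA
    k0 = int(np.floor(data.min() / b))
    k1 = int(np.floor(data.max() / b)) + 1
    edges = np.arange(k0, k1 + 1) * b
    counts, _ = np.histogram(data, bins=edges)
    return AmplitudeHistogram(bin_edges_pA=edges, counts=counts,
                              included_sweep_ids=tuple(ids),
                              active_only=active_only)


@dataclass
class GaussianPeaks:
    means_pA: np.ndarray
    sds_pA: np.ndarray
    weights: np.ndarray
    dominant_open_peak_pA: float


def fit_histogram_peaks(h: AmplitudeHistogram, cfg: AnalysisConfig, *,
                        voltage_mV: float = 60.0,
                        max_iter: int = 300) -> GaussianPeaks:
    """Gaussian mixture fit of the histogram, one component per ladder level.

    Expectation-maximization on the binned samples with a deterministic
    initialization (means at the voltage-scaled ladder amplitudes, common
    starting width), so the fit is reproducible.  The dominant open peak is
    the non-closed component with the largest weight.
    """
    if h.total == 0:
        raise ValueError("empty histogram")
    x = h.centers_pA
    w_data = h.counts.astype(float)
    ladder = cfg.ladder_at(voltage_mV)
    k = ladder.size
    mu = ladder.astype(float).copy()
    sd = np.full(k, max(0.02, cfg.histogram_bin_pA))
    # initial weights: data mass nearest to each component
    assign = np.argmin(np.abs(x[:, None] - mu[None, :]), axis=1)
    pi = np.array([w_data[assign == j].sum() for j in range(k)])
    pi = np.maximum(pi, 1e-6)
    pi /= pi.sum()
    sd_floor = cfg.histogram_bin_pA / 2.0
    n_tot = w_data.sum()
    prev_ll = -np.inf
    for _ in range(max_iter):
        dens = (pi[None, :] / (sd[None, :] * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2))
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(w_data * np.log(tot)))
        resp = dens / tot[:, None]
        nk = (w_data[:, None] * resp).sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = ((w_data[:, None] * resp * x[:, None]).sum(axis=0)) / nk
        var = ((w_data[:, None] * resp * (x[:, None] - mu[None, :]) ** 2)
               .sum(axis=0)) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        pi = nk / n_tot
        if abs(ll - prev_ll) < 1e-10 * max(1.0, abs(ll)):
            break
        prev_ll = ll
    open_boundary = ladder[1] / 2.0
    open_mask = (mu > open_boundary) & (pi > 0.01)
    if not open_mask.any():
        raise NoOpenPeakError("no open-level component exceeds weight 0.01")
    dominant = float(mu[open_mask][np.argmax(pi[open_mask])])
    return GaussianPeaks(means_pA=mu, sds_pA=sd, weights=pi,
                         dominant_open_peak_pA=dominant)


# --------------------------------------------------------------------------
# dwell summaries


@dataclass
class DwellSummary:
    """Per-level time accounting over a set of idealized traces.

    ``table`` has one row per ladder level: total_s, mean_dwell_s,
    event_count and percent_of_open_time (open levels; sums to 100).  The
    closed-level mean excludes each sweep's first-latency interval.
    """

    table: pd.DataFrame
    closed_mean_excluding_first_latency_s: float
    first_latencies_s: np.ndarray
    first_latency_mean_s: float
    first_latency_se_s: float | None
    n_traces: int
    n_active: int


def summarize_dwells(traces: Sequence[IdealizedTrace],
                     cfg: AnalysisConfig) -> DwellSummary:
    """Aggregate dwell statistics across idealized traces."""
    if not traces:
        raise ValueError("need at least one trace")
    k = len(cfg.level_amplitudes_pA)
    totals = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    closed_excl: list[float] = []
    latencies: list[float | None] = []
    for tr in traces:
        lat = first_latency(tr)
        latencies.append(lat)
        for j, (level, start, dur) in enumerate(tr.events):
            totals[level] += dur
            counts[level] += 1
            if level == 0:
                is_latency = (j == 0 and lat is not None) or lat is None
                if not is_latency:
                    closed_excl.append(dur)
    open_total = totals[1:].sum()
    if open_total <= 0:
        raise ValueError("no open time")
    percent = np.full(k, np.nan)
    percent[1:] = 100.0 * totals[1:] / open_total
    with np.errstate(invalid="ignore"):
        mean_dwell = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame({
        "level_index": np.arange(k),
        "amplitude_pA": np.asarray(cfg.level_amplitudes_pA),
        "total_s": totals,
        "mean_dwell_s": mean_dwell,
        "event_count": counts,
        "percent_of_open_time": percent,
    })
    lat_vals = [v for v in latencies if v is not None]
    lat_mean, lat_se, _ = mean_se(lat_vals) if lat_vals else (np.nan, None, 0)
    return DwellSummary(
        table=table,
        closed_mean_excluding_first_latency_s=(float(np.mean(closed_excl))
                                               if closed_excl else np.nan),
        first_latencies_s=np.array([np.nan if v is None else v
                                    for v in latencies]),
        first_latency_mean_s=lat_mean,
        first_latency_se_s=lat_se,
        n_traces=len(traces),
        n_active=len(lat_vals),
    )


# --------------------------------------------------------------------------
# slope conductance


@dataclass
class SlopeFit:
    """Slope conductance through the K+ reversal anchor."""

    gamma_pS: float
    reversal_mV: float
    points: tuple[tuple[float, float], ...]


def estimate_slope_conductance(
    points: Sequence[tuple[float, float]], cfg: AnalysisConfig, *,
    reversal_mV: float | None = None,
) -> SlopeFit:
    """Least-squares line through (voltage, amplitude) points constrained
    to pass through (reversal, 0); slope reported in pS.

    With a single point this is the chord conductance through the anchor.
    """
    if not points:
        raise ValueError("need at least one (voltage, amplitude) point")
    rev = cfg.reversal_mV if reversal_mV is None else reversal_mV
    v = np.array([p[0] for p in points], float)
    a = np.array([p[1] for p in points], float)
    dv = v - rev
    denom = float(np.sum(dv * dv))
    if denom == 0:
        raise ValueError("all points sit at the reversal potential; "
                         "slope undefined")
    slope_pA_per_mV = float(np.sum(a * dv) / denom)
    gamma = 1000.0 * slope_pA_per_mV
    if gamma <= 0:
        log.warning("non-positive slope conductance %.3g pS", gamma)
    return SlopeFit(gamma_pS=gamma, reversal_mV=rev,
                    points=tuple((float(x), float(y)) for x, y in points))
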