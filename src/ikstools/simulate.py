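"""Synthetic data generator.

Emulates the three kinds of recordings the analysis consumes:

* single-channel sweeps over a subconductance ladder — a renewal (semi-
  Markov) gating process with exponential sojourns, a shifted-exponential
  first latency, blank sweeps, interburst closures, ohmic voltage scaling
  of the level amplitudes, Gaussian noise and 4-pole Bessel low-pass
  filtering;
* whole-cell isochronal activation families with tail currents, driven by
  a Boltzmann activation curve B(V) = 1/(1 + exp((V1/2 - V)/k));
* per-sweep peak-current diaries decaying with cumulative UV exposure
  (two-phase: fast crosslinking K_XL plus slow rundown K_RD).

Sojourn levels are drawn i.i.d. with visit probability proportional to
occupancy/mean-dwell, so the expected fraction of open time spent at each
level equals the configured ``occupancy_fractions`` exactly, for any dwell
means; adjacent same-level sojourns are merged in the emitted event log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from .events import levels_from_events
from .trace_io import ProtocolStep, SweepSet, write_sweep_set
from .uv_kinetics import DiarySeries

__all__ = [
    "ParameterError",
    "GatingModel",
    "MacroModel",
    "UVDecayModel",
    "simulate_single_channel_sweeps",
    "simulate_macroscopic_family",
    "simulate_uv_diary",
    "simulate_uv_sweep_set",
    "make_fixture_suite",
    "bessel_lowpass",
]

REFERENCE_VOLTAGE_MV = 60.0


class ParameterError(ValueError):
    """A simulator parameter set is inconsistent."""


def bessel_lowpass(x: np.ndarray, fs: float, cutoff_Hz: float) -> np.ndarray:
    """4-pole Bessel low-pass along the last axis (causal, as in hardware)."""
    sos = signal.bessel(4, cutoff_Hz, fs=fs, output="sos")
    return signal.sosfilt(sos, x, axis=-1)


@dataclass(frozen=True)
class GatingModel:
    """Single-channel gating parameters at the +60 mV reference voltage.

    ``level_amplitudes_pA`` includes the closed level 0 first; amplitudes
    at voltage V scale as level * (V - reversal)/(60 - reversal).
    ``occupancy_fractions`` (over open levels, summing to 1) prescribe the
    expected share of open time per sublevel; ``mean_dwell_s`` gives the
    mean sojourn per ladder level (index 0 = intraburst closed).  First
    latency is offset + Exp(mean - offset); a sweep is blank with
    probability ``p_blank`` (or when the latency outlasts the test step).
    ``burst_end_rate`` (1/s of open time) sets how often the channel falls
    back to the closed level between bursts.
    """

    level_amplitudes_pA: tuple[float, ...]
    occupancy_fractions: tuple[float, ...]
    mean_dwell_s: tuple[float, ...]
    first_latency_mean_s: float
    first_latency_offset_s: float = 0.3
    p_blank: float = 0.0
    burst_end_rate: float = 2.0
    slope_conductance_pS: float | None = None
    reversal_mV: float = -84.0
    noise_sd_pA: float = 0.04
    filter_cutoff_Hz: float | None = 200.0

    def __post_init__(self) -> None:
        lad = np.asarray(self.level_amplitudes_pA, float)
        occ = np.asarray(self.occupancy_fractions, float)
        tau = np.asarray(self.mean_dwell_s, float)
        if lad[0] != 0.0 or np.any(np.diff(lad) <= 0):
            raise ParameterError("level ladder must start at 0 and ascend strictly")
        if occ.shape != (lad.size - 1,):
            raise ParameterError("occupancy_fractions must cover the open levels")
        if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-9:
            raise ParameterError("occupancy_fractions must be >= 0 and sum to 1 "
                                 f"(sum = {occ.sum():.12g})")
        if tau.shape != (lad.size,) or np.any(tau <= 0):
            raise ParameterError("mean_dwell_s must be positive, one per level")
        if self.first_latency_offset_s < 0:
            raise ParameterError("first_latency_offset_s must be >= 0")
        if self.first_latency_mean_s <= self.first_latency_offset_s:
            raise ParameterError("first latency mean must exceed its offset")
        if not 0.0 <= self.p_blank <= 1.0:
            raise ParameterError("p_blank must lie in [0, 1]")
        if self.burst_end_rate < 0:
            raise ParameterError("burst_end_rate must be >= 0")

    # -- derived ----------------------------------------------------------
    def amplitude_scale(self, voltage_mV: float) -> float:
        return ((voltage_mV - self.reversal_mV)
                / (REFERENCE_VOLTAGE_MV - self.reversal_mV))

    @property
    def dominant_level_index(self) -> int:
        """Ladder index of the open level with the largest occupancy."""
        return 1 + int(np.argmax(self.occupancy_fractions))

    @property
    def expected_gamma_pS(self) -> float:
        """Chord conductance of the dominant sublevel through the reversal."""
        amp = self.level_amplitudes_pA[self.dominant_level_index]
        return 1000.0 * amp / (REFERENCE_VOLTAGE_MV - self.reversal_mV)

    def visit_distribution(self) -> np.ndarray:
        """Per-level sojourn draw probabilities (index 0 = closed).

        Chosen so expected time fractions are: closed
        c* = tau_c*r/(1 + tau_c*r) with r = burst_end_rate, and
        (1 - c*) * occupancy_k for open level k.
        """
        tau = np.asarray(self.mean_dwell_s, float)
        r = self.burst_end_rate
        c_star = tau[0] * r / (1.0 + tau[0] * r) if r > 0 else 0.0
        fractions = np.concatenate([[c_star],
                                    (1.0 - c_star) * np.asarray(self.occupancy_fractions)])
        rates = np.where(fractions > 0, fractions / tau, 0.0)
        return rates / rates.sum()


def _draw_sojourns(rng: np.random.Generator, model: GatingModel,
                   total_s: float) -> list[tuple[int, float]]:
    """(level, duration) sojourns covering at least ``total_s`` of time.

    The first sojourn is an open level (it is the channel's first opening);
    subsequent levels are i.i.d. from the visit distribution with adjacent
    repeats merged.
    """
    q = model.visit_distribution()
    tau = np.asarray(model.mean_dwell_s, float)
    q_open = q[1:].copy()
    if q_open.sum() <= 0:
        raise ParameterError("model has no open-level occupancy")
    q_open /= q_open.sum()
    levels_idx = np.arange(q.size)
    out: list[tuple[int, float]] = []
    t = 0.0
    level = int(rng.choice(levels_idx[1:], p=q_open))
    while True:
        dur = float(rng.exponential(tau[level]))
        if out and out[-1][0] == level:
            out[-1] = (level, out[-1][1] + dur)
        else:
            out.append((level, dur))
        t += dur
        if t >= total_s:
            break
        level = int(rng.choice(levels_idx, p=q))
    return out


def simulate_single_channel_sweeps(
    m: GatingModel,
    protocol: Sequence[ProtocolStep],
    n_sweeps: int,
    fs: float,
    seed: int,
    *,
    cell_id: str = "sim",
    construct: str = "custom",
) -> SweepSet:
    """Simulate a single-channel sweep set; reproducible given ``seed``.

    The returned set carries the ground-truth gating ``event_logs`` (one
    list of (level, start_s, duration_s) per sweep, timed from test-step
    onset) and per-sweep ``first_latencies_s`` (NaN for blanks).
    """
    if n_sweeps < 1:
        raise ParameterError("n_sweeps >= 1 violated")
    if m.filter_cutoff_Hz is not None and fs < 2 * m.filter_cutoff_Hz:
        raise ParameterError(
            f"sampling rate {fs} Hz is below twice the filter cutoff")
    protocol = list(protocol)
    volts = [p.voltage_mV for p in protocol]
    test_idx = int(np.argmax(volts))
    counts = [int(round(p.duration_s * fs)) for p in protocol]
    edges = np.concatenate([[0], np.cumsum(counts)]).astype(int)
    n_samples = int(edges[-1])
    t0 = edges[test_idx] / fs                      # test-step onset
    step_dur = protocol[test_idx].duration_s       # latency censoring window
    span = n_samples / fs - t0                     # test step + everything after

    # per-sample amplitude scale from the command voltage of each step
    scale = np.empty(n_samples)
    for (a, b), p in zip(zip(edges[:-1], edges[1:]), protocol):
        scale[a:b] = m.amplitude_scale(p.voltage_mV)

    ladder = np.asarray(m.level_amplitudes_pA)
    rng = np.random.default_rng(seed)
    sweeps = np.zeros((n_sweeps, n_samples))
    logs: list[list[tuple[int, float, float]]] = []
    latencies = np.full(n_sweeps, np.nan)
    n_pre = int(edges[test_idx])

    for i in range(n_sweeps):
        blank = rng.random() < m.p_blank
        latency = (m.first_latency_offset_s
                   + float(rng.exponential(m.first_latency_mean_s
                                           - m.first_latency_offset_s)))
        if blank or latency >= step_dur:
            logs.append([(0, 0.0, span)])
            continue
        latencies[i] = latency
        sojourns = _draw_sojourns(rng, m, span - latency)
        log = [(0, 0.0, latency)] if latency > 0 else []
        t = latency
        for level, dur in sojourns:
            dur = min(dur, span - t)
            log.append((level, t, dur))
            t += dur
            if t >= span:
                break
        logs.append(log)
        lv = levels_from_events(log, fs, n_samples - n_pre)
        sweeps[i, n_pre:] = ladder[lv] * scale[n_pre:]

    if m.noise_sd_pA > 0:
        sweeps += rng.normal(0.0, m.noise_sd_pA, sweeps.shape)
    if m.filter_cutoff_Hz is not None:
        sweeps = bessel_lowpass(sweeps, fs, m.filter_cutoff_Hz)

    return SweepSet(
        cell_id=cell_id, construct=construct, sampling_rate_Hz=fs,
        protocol=protocol, sweeps=sweeps, unit="pA", seed=seed,
        event_logs=logs, first_latencies_s=latencies,
    )


# --------------------------------------------------------------------------
# whole-cell isochronal families


@dataclass(frozen=True)
class MacroModel:
    """Whole-cell activation model: Boltzmann steady state, single-
    exponential activation toward it, exponential tail deactivation."""

    v_half_mV: float
    k_mV: float
    g_max_nS: float = 60.0
    act_tau_s: float = 0.7
    deact_tau_s: float = 0.15
    tail_voltage_mV: float = -40.0
    reversal_mV: float = -83.0
    holding_mV: float = -80.0
    holding_s: float = 0.25
    step_s: float = 4.0
    tail_s: float = 0.75
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.k_mV <= 0:
            raise ParameterError("k_mV must be > 0")
        if self.g_max_nS <= 0:
            raise ParameterError("g_max_nS must be > 0")

    def boltzmann(self, voltage_mV: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v_half_mV - np.asarray(voltage_mV))
                                   / self.k_mV))


def simulate_macroscopic_family(
    m: MacroModel,
    voltages: Sequence[float],
    fs: float,
    seed: int,
    *,
    cell_id: str = "sim",
    construct: str = "custom",
) -> SweepSet:
    """One sweep per step voltage: activation for ``step_s`` seconds then a
    common tail step; currents in nA; multiplicative noise of ``noise_cv``."""
    voltages = np.asarray(voltages, float)
    if voltages.size == 0:
        raise ParameterError("voltage list must be non-empty")
    protocol = [ProtocolStep(m.holding_mV, m.holding_s),
                ProtocolStep(float(voltages.max()), m.step_s),
                ProtocolStep(m.tail_voltage_mV, m.tail_s)]
    counts = [int(round(p.duration_s * fs)) for p in protocol]
    n_hold, n_step, n_tail = counts
    t_step = np.arange(n_step) / fs
    t_tail = np.arange(n_tail) / fs
    rng = np.random.default_rng(seed)
    sweeps = np.zeros((voltages.size, sum(counts)))
    for i, v in enumerate(voltages):
        b = m.boltzmann(v)
        i_inf = m.g_max_nS * b * (v - m.reversal_mV) / 1000.0
        act = i_inf * (1.0 - np.exp(-t_step / m.act_tau_s))
        b_end = b * (1.0 - np.exp(-m.step_s / m.act_tau_s))
        i_tail0 = m.g_max_nS * b_end * (m.tail_voltage_mV - m.reversal_mV) / 1000.0
        tail = i_tail0 * np.exp(-t_tail / m.deact_tau_s)
        sweeps[i, n_hold:n_hold + n_step] = act
        sweeps[i, n_hold + n_step:] = tail
    if m.noise_cv > 0:
        sweeps *= 1.0 + m.noise_cv * rng.standard_normal(sweeps.shape)
    return SweepSet(
        cell_id=cell_id, construct=construct, sampling_rate_Hz=fs,
        protocol=protocol, sweeps=sweeps, unit="nA", seed=seed,
        test_voltages_mV=voltages,
    )


# --------------------------------------------------------------------------
# UV crosslinking / rundown diaries


@dataclass(frozen=True)
class UVDecayModel:
    """Normalized peak current vs cumulative UV exposure.

    Expected value at cumulative exposure t:
    plateau + (1 - plateau) * [f * exp(-K_XL t) + (1 - f) * exp(-K_RD t)],
    with f = ``frac_fast``.  Exposure accrues ``flash_s`` per flashed sweep
    starting at sweep ``baseline_sweeps`` + 1.
    """

    k_xl_per_s: float
    k_rd_per_s: float
    frac_fast: float = 0.85
    plateau: float = 0.0
    baseline_sweeps: int = 5
    flash_s: float = 0.3
    n_sweeps: int = 30
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.k_xl_per_s < 0 or self.k_rd_per_s < 0:
            raise ParameterError("rate constants must be >= 0")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ParameterError("frac_fast must lie in [0, 1]")
        if not 0.0 <= self.plateau < 1.0:
            raise ParameterError("plateau must lie in [0, 1)")
        if self.n_sweeps <= self.baseline_sweeps:
            raise ParameterError("n_sweeps must exceed baseline_sweeps")

    def expected(self, cumulative_uv_s: np.ndarray) -> np.ndarray:
        t = np.asarray(cumulative_uv_s, float)
        f = self.frac_fast
        return self.plateau + (1.0 - self.plateau) * (
            f * np.exp(-self.k_xl_per_s * t)
            + (1.0 - f) * np.exp(-self.k_rd_per_s * t))


def simulate_uv_diary(
    u: UVDecayModel,
    seed: int,
    *,
    cell_id: str = "sim",
    construct: str = "custom",
    peak_nA: float = 10.0,
    initial_nA: float = 0.5,
) -> DiarySeries:
    """Per-sweep peak-current diary; multiplicative noise of ``noise_cv``."""
    rng = np.random.default_rng(seed)
    idx = np.arange(1, u.n_sweeps + 1)
    t = np.maximum(0, idx - u.baseline_sweeps) * u.flash_s
    peaks = peak_nA * u.expected(t)
    if u.noise_cv > 0:
        peaks = peaks * (1.0 + u.noise_cv * rng.standard_normal(peaks.shape))
    return DiarySeries(
        cell_id=cell_id, construct=construct, peaks=peaks,
        baseline_sweeps=u.baseline_sweeps, flash_s=u.flash_s, unit="nA",
        initial_current=initial_nA,
    )


def simulate_uv_sweep_set(
    u: UVDecayModel,
    seed: int,
    fs: float = 2000.0,
    *,
    cell_id: str = "sim",
    construct: str = "custom",
    peak_nA: float = 10.0,
    initial_nA: float = 0.5,
    act_tau_s: float = 0.7,
) -> SweepSet:
    """Full whole-cell sweeps for the UV protocol (flash at -90 mV, 4 s
    activation to +60 mV, tail), with peak amplitude following the decay."""
    rng = np.random.default_rng(seed)
    protocol = [ProtocolStep(-90.0, 0.25), ProtocolStep(60.0, 4.0),
                ProtocolStep(-40.0, 0.75)]
    counts = [int(round(p.duration_s * fs)) for p in protocol]
    n_hold, n_step, n_tail = counts
    t_step = np.arange(n_step) / fs
    rise = (1.0 - np.exp(-t_step / act_tau_s)) / (1.0 - np.exp(-4.0 / act_tau_s))
    idx = np.arange(1, u.n_sweeps + 1)
    t_uv = np.maximum(0, idx - u.baseline_sweeps) * u.flash_s
    amps = peak_nA * u.expected(t_uv)
    if u.noise_cv > 0:
        amps = amps * (1.0 + u.noise_cv * rng.standard_normal(amps.shape))
    sweeps = np.zeros((u.n_sweeps, sum(counts)))
    for i, amp in enumerate(amps):
        sweeps[i, n_hold:n_hold + n_step] = initial_nA + (amp - initial_nA) * rise
        sweeps[i, n_hold + n_step:] = (0.3 * amp
                                       * np.exp(-np.arange(n_tail) / fs / 0.15))
    flashes = np.where(idx > u.baseline_sweeps, u.flash_s, 0.0)
    return SweepSet(
        cell_id=cell_id, construct=construct, sampling_rate_Hz=fs,
        protocol=protocol, sweeps=sweeps, unit="nA", uv_flash_s=flashes,
        seed=seed,
    )


# --------------------------------------------------------------------------
# packaged fixture suite


def make_fixture_suite(outdir: str | Path, seed: int) -> dict:
    """Write one fixture per packaged construct plus a manifest.

    Single-channel constructs get sweep sets, KCNQ1 a whole-cell G-V
    family, and the wild-type EQ + KCNE1 rundown a UV sweep set; all files
    are in the text dialect and byte-reproducible given the seed.
    """
    from . import constructs as C

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []

    def _sub(i: int) -> int:
        return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))

    order = 0
    for name, gm in C.SINGLE_CHANNEL.items():
        protocol = C.single_channel_protocol(name)
        s = simulate_single_channel_sweeps(
            gm, protocol, n_sweeps=10, fs=5000.0, seed=_sub(order),
            cell_id=f"{name}-fixture", construct=name)
        path = outdir / f"sc_{name.replace('+', '_')}.sweeps"
        write_sweep_set(s, path)
        entries.append({"file": path.name, "construct": name,
                        "kind": "single_channel", "seed": _sub(order)})
        order += 1

    mm = C.MACRO["KCNQ1"]
    fam = simulate_macroscopic_family(
        mm, np.arange(-80.0, 101.0, 20.0), fs=1000.0, seed=_sub(order),
        cell_id="KCNQ1-fixture", construct="KCNQ1")
    path = outdir / "gv_KCNQ1.sweeps"
    write_sweep_set(fam, path)
    entries.append({"file": path.name, "construct": "KCNQ1",
                    "kind": "gv_family", "seed": _sub(order)})
    order += 1

    um = C.RUNDOWN["EQ+KCNE1"]
    uvset = simulate_uv_sweep_set(um, _sub(order), cell_id="EQ_KCNE1-fixture",
                                  construct="EQ+KCNE1")
    path = outdir / "uv_EQ_KCNE1.sweeps"
    write_sweep_set(uvset, path)
    entries.append({"file": path.name, "construct": "EQ+KCNE1",
                    "kind": "uv_diary_sweeps", "seed": _sub(order)})

    manifest = {"seed": seed, "fixtures": entries}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
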