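"""Tail-current G-V extraction and per-cell Boltzmann fits.

Conductance-voltage relations come from isochronal activation families:
the instantaneous tail current after each test step is proportional to the
open probability reached at step end, so normalized tail amplitudes trace
B(V).  Each cell is fit with a Boltzmann sigmoid

    g(V) = 1 / (1 + exp((V1/2 - V) / k)),   k > 0,

and midpoints are averaged across cells per construct (never pooled fits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._stats import mean_se
from .trace_io import AnalysisConfig, ConfigurationError, SweepSet, get_logger

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "extract_tail_amplitudes",
    "boltzmann",
    "fit_boltzmann",
    "summarize_v12",
]

log = get_logger("macroscopic")


def boltzmann(v: np.ndarray | float, v_half: float, k: float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, float)) / k))


@dataclass
class GVCurve:
    """Normalized tail-current conductance vs test voltage for one cell."""

    voltages_mV: np.ndarray
    g_norm: np.ndarray
    tail_voltage_mV: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, float)
        self.g_norm = np.asarray(self.g_norm, float)
        order = np.argsort(self.voltages_mV)
        self.voltages_mV = self.voltages_mV[order]
        self.g_norm = self.g_norm[order]
        if np.any(np.diff(self.voltages_mV) <= 0):
            raise ValueError("test voltages must be distinct")
        if np.any(self.g_norm < -0.05) or np.any(self.g_norm > 1.05):
            raise ValueError("normalized conductance outside [0, 1.05]")


@dataclass
class BoltzmannFit:
    v_half_mV: float
    k_mV: float
    residual_norm: float
    cell_id: str = ""
    converged: bool = True
    extrapolated: bool = False
    amplitude: float = 1.0

    def predict(self, v: np.ndarray | float) -> np.ndarray | float:
        return boltzmann(v, self.v_half_mV, self.k_mV)


def extract_tail_amplitudes(s: SweepSet, cfg: AnalysisConfig) -> GVCurve:
    """Per-sweep tail amplitudes, baseline-subtracted and max-normalized.

    Tail amplitude = signed peak within ``cfg.tail_window_s`` after tail
    onset, relative to the pre-step holding baseline; the protocol must end
    in a tail step common to all sweeps.
    """
    slices = s.step_slices()
    t_idx = s.test_step_index
    if t_idx == len(s.protocol) - 1:
        raise ConfigurationError("protocol does not end in a tail step")
    tail_sl = slices[-1]
    n_win = max(1, int(round(cfg.tail_window_s * s.sampling_rate_Hz)))
    amps = np.empty(s.n_sweeps)
    for i in range(s.n_sweeps):
        baseline = float(s.sweeps[i, slices[0]].mean()) if t_idx > 0 else 0.0
        seg = s.sweeps[i, tail_sl][:n_win] - baseline
        amps[i] = seg[np.argmax(np.abs(seg))]
    peak = np.max(np.abs(amps))
    if peak <= 0:
        raise ValueError("zero maximum tail amplitude; cannot normalize")
    g = np.abs(amps) / peak
    voltages = (s.test_voltages_mV if s.test_voltages_mV is not None
                else np.full(s.n_sweeps, s.test_step.voltage_mV))
    return GVCurve(voltages_mV=voltages, g_norm=g,
                   tail_voltage_mV=s.protocol[-1].voltage_mV, cell_id=s.cell_id)


def fit_boltzmann(c: GVCurve, *, free_amplitude: bool = True) -> BoltzmannFit:
    """Deterministic least-squares Boltzmann fit of one cell's G-V curve.

    Initialized at the interpolated half-maximum crossing with k = 10 mV.
    By default a free amplitude (maximal conductance) multiplies the
    sigmoid: max-normalized tail data saturate slightly below the true
    asymptote, and the nuisance scale removes the midpoint bias this would
    otherwise cause.  The reported relation is still g(V1/2) = 0.5 of the
    fitted sigmoid.  Non-convergence is flagged, never silent.
    """
    v, g = c.voltages_mV, c.g_norm
    if v.size < 4:
        raise ValueError("need at least 4 G-V points")
    # deterministic initialization: first crossing of 0.5
    above = np.flatnonzero(g >= 0.5)
    if above.size and above[0] > 0:
        i = above[0]
        v0 = float(np.interp(0.5, [g[i - 1], g[i]], [v[i - 1], v[i]]))
    elif above.size:
        v0 = float(v[0])
    else:
        v0 = float(v[-1])
    spans = g.min() < 0.5 < g.max()

    if free_amplitude:
        def resid(theta):
            return theta[2] * boltzmann(v, theta[0], theta[1]) - g
        x0 = [v0, 10.0, float(max(g.max(), 0.5))]
        bounds = ([-500.0, 1e-2, 0.1], [500.0, 500.0, 2.0])
    else:
        def resid(theta):
            return boltzmann(v, theta[0], theta[1]) - g
        x0 = [v0, 10.0]
        bounds = ([-500.0, 1e-2], [500.0, 500.0])

    res = least_squares(resid, x0, bounds=bounds,
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    fit = BoltzmannFit(
        v_half_mV=float(res.x[0]), k_mV=float(res.x[1]),
        residual_norm=float(np.linalg.norm(res.fun)), cell_id=c.cell_id,
        converged=bool(res.success), extrapolated=not spans,
        amplitude=float(res.x[2]) if free_amplitude else 1.0)
    if not res.success:
        log.warning("Boltzmann fit did not converge for cell %s: %s",
                    c.cell_id, res.message)
    return fit


def summarize_v12(
    fits_by_construct: Mapping[str, Sequence[BoltzmannFit]],
) -> pd.DataFrame:
    """Per-construct mean ± SE of V1/2 (and k) across cells, with n."""
    rows = []
    for construct, fits in fits_by_construct.items():
        if not fits:
            log.warning("construct %s has no fits; omitted", construct)
            continue
        vm, vse, n = mean_se([f.v_half_mV for f in fits])
        km, kse, _ = mean_se([f.k_mV for f in fits])
        rows.append({"construct": construct, "n": n,
                     "v_half_mean_mV": vm, "v_half_se_mV": vse,
                     "k_mean_mV": km, "k_se_mV": kse})
    return pd.DataFrame(rows)
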