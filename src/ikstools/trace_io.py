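"""Sweep-set and configuration I/O.

The on-disk sweep-set dialect is a UTF-8 text container: a ``key: value``
header block terminated by a ``---`` line, followed by one comma-separated
row of current samples per sweep.  It is diffable, language-neutral and
carries everything the analysis needs: unit (pA or nA), sampling rate, the
voltage protocol, per-sweep UV flash durations and (optionally) per-sweep
test-step voltages for isochronal families.

Currents are pA for single-channel sets and may be nA for whole-cell sets;
voltages are mV, times are s.  No conversion ever happens implicitly.
Sample ``i`` covers ``[i/fs, (i+1)/fs)`` seconds from sweep start.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolStep",
    "SweepSet",
    "AnalysisConfig",
    "SweepFormatError",
    "SweepValidationError",
    "ConfigurationError",
    "read_sweep_set",
    "write_sweep_set",
    "load_config",
    "nernst_reversal_mV",
    "get_logger",
]

_FORMAT_VERSION = "ikstools-sweepset-v1"

# stderr logging with per-stage prefixes; every stage asks for its own child
_root_logger = logging.getLogger("ikstools")
if not _root_logger.handlers:  # pragma: no cover - import-time wiring
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[ikstools.%(name)s] %(levelname)s: %(message)s"))
    _root_logger.addHandler(_h)
    _root_logger.setLevel(logging.WARNING)


def get_logger(stage: str) -> logging.Logger:
    """Return the stderr logger for a pipeline stage (e.g. ``'single_channel'``)."""
    return logging.getLogger(stage)


class SweepFormatError(ValueError):
    """A sweep-set file is malformed (missing or unparsable header field)."""


class SweepValidationError(ValueError):
    """A sweep set violates its invariants (lengths, counts, units)."""


class ConfigurationError(ValueError):
    """An analysis configuration is inconsistent with the data or itself."""


def nernst_reversal_mV(k_out_mM: float = 5.0, k_in_mM: float = 135.0,
                       temp_C: float = 22.0) -> float:
    """Nernst K+ reversal potential in mV.

    Defaults are the single-channel solutions (5 mM K+ pipette / 135 mM K+
    bath) at room temperature, giving about -84 mV.
    """
    R, F = 8.31446, 96485.332
    T = temp_C + 273.15
    return 1000.0 * R * T / F * np.log(k_out_mM / k_in_mM)


@dataclass(frozen=True)
class ProtocolStep:
    """One command-voltage step: ``voltage_mV`` held for ``duration_s``."""

    voltage_mV: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise SweepValidationError(
                f"ProtocolStep duration_s must be > 0, got {self.duration_s}")


def _protocol_samples(protocol: Sequence[ProtocolStep], fs: float) -> list[int]:
    """Per-step sample counts; errors if a duration is off the sample grid."""
    counts = []
    for i, step in enumerate(protocol):
        n = step.duration_s * fs
        if abs(n - round(n)) > 1e-6:
            raise SweepValidationError(
                f"protocol step {i}: duration {step.duration_s} s is not an "
                f"integer number of samples at {fs} Hz")
        counts.append(int(round(n)))
    return counts


@dataclass
class SweepSet:
    """A cell's sweeps plus protocol and sampling metadata; the unit of I/O.

    ``sweeps`` is an (n_sweeps, n_samples) float array in ``unit`` (pA or
    nA).  ``uv_flash_s`` gives the UV flash applied before each sweep (0 =
    no flash).  ``test_voltages_mV``, when present, overrides the test-step
    command voltage per sweep (isochronal activation families).

    ``event_logs`` / ``first_latencies_s`` are simulator side-channels
    (ground-truth gating events); they are never serialized.
    """

    cell_id: str
    construct: str
    sampling_rate_Hz: float
    protocol: list[ProtocolStep]
    sweeps: np.ndarray
    unit: str = "pA"
    uv_flash_s: np.ndarray | None = None
    test_voltages_mV: np.ndarray | None = None
    seed: int | None = None
    # simulator ground truth, not part of the file format
    event_logs: list | None = field(default=None, repr=False, compare=False)
    first_latencies_s: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2 or self.sweeps.shape[0] < 1:
            raise SweepValidationError("n_sweeps >= 1 violated")
        if self.unit not in ("pA", "nA"):
            raise SweepValidationError(f"unit must be pA or nA, got {self.unit!r}")
        if not self.protocol:
            raise SweepValidationError("protocol must contain at least one step")
        counts = _protocol_samples(self.protocol, self.sampling_rate_Hz)
        n_expected = int(sum(counts))
        if self.sweeps.shape[1] != n_expected:
            raise SweepValidationError(
                f"sweep length mismatch: protocol implies {n_expected} samples "
                f"but sweeps hold {self.sweeps.shape[1]}")
        if self.uv_flash_s is None:
            self.uv_flash_s = np.zeros(self.n_sweeps)
        else:
            self.uv_flash_s = np.asarray(self.uv_flash_s, dtype=float)
            if self.uv_flash_s.shape != (self.n_sweeps,):
                raise SweepValidationError(
                    f"uv_flash_s must have one entry per sweep "
                    f"({self.n_sweeps}), got {self.uv_flash_s.shape}")
        if self.test_voltages_mV is not None:
            self.test_voltages_mV = np.asarray(self.test_voltages_mV, dtype=float)
            if self.test_voltages_mV.shape != (self.n_sweeps,):
                raise SweepValidationError(
                    "test_voltages_mV must have one entry per sweep")

    # -- geometry ---------------------------------------------------------
    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    def step_slices(self) -> list[slice]:
        """Half-open sample slice of each protocol step."""
        counts = _protocol_samples(self.protocol, self.sampling_rate_Hz)
        edges = np.concatenate([[0], np.cumsum(counts)]).astype(int)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    @property
    def test_step_index(self) -> int:
        """Index of the depolarizing test step (the most positive command)."""
        volts = [p.voltage_mV for p in self.protocol]
        i = int(np.argmax(volts))
        if len(self.protocol) > 1 and volts.count(max(volts)) > 1:
            raise ConfigurationError("protocol has no unique depolarizing test step")
        return i

    @property
    def test_step(self) -> ProtocolStep:
        return self.protocol[self.test_step_index]

    def test_step_slice(self) -> slice:
        return self.step_slices()[self.test_step_index]

    def test_voltage(self, sweep: int) -> float:
        if self.test_voltages_mV is not None:
            return float(self.test_voltages_mV[sweep])
        return self.test_step.voltage_mV


# --------------------------------------------------------------------------
# file dialect


def _format_protocol(protocol: Sequence[ProtocolStep]) -> str:
    return ";".join(f"{p.voltage_mV:.10g}:{p.duration_s:.10g}" for p in protocol)


def _parse_protocol(text: str) -> list[ProtocolStep]:
    steps = []
    for part in text.split(";"):
        try:
            v, d = part.split(":")
            steps.append(ProtocolStep(float(v), float(d)))
        except (ValueError, TypeError) as exc:
            raise SweepFormatError(f"cannot parse protocol entry {part!r}") from exc
    return steps


def write_sweep_set(s: SweepSet, path: str | Path) -> Path:
    """Write ``s`` in the text dialect; returns the path.

    Metadata round-trips bit-equal; samples are written with 9 significant
    digits (beyond any recording instrument's resolution).
    """
    path = Path(path)
    lines = [
        f"# {_FORMAT_VERSION}",
        f"cell_id: {s.cell_id}",
        f"construct: {s.construct}",
        f"unit: {s.unit}",
        f"sampling_rate_Hz: {s.sampling_rate_Hz:.10g}",
        f"protocol: {_format_protocol(s.protocol)}",
        "uv_flash_s: " + ",".join(f"{v:.10g}" for v in s.uv_flash_s),
    ]
    if s.test_voltages_mV is not None:
        lines.append("test_voltages_mV: "
                     + ",".join(f"{v:.10g}" for v in s.test_voltages_mV))
    if s.seed is not None:
        lines.append(f"seed: {s.seed}")
    lines.append(f"n_sweeps: {s.n_sweeps}")
    lines.append("---")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, s.sweeps, fmt="%.9g", delimiter=",")
    return path


_REQUIRED_FIELDS = ("cell_id", "construct", "unit", "sampling_rate_Hz",
                    "protocol", "n_sweeps")


def read_sweep_set(path: str | Path) -> SweepSet:
    """Read a sweep set, validating every invariant (see :class:`SweepSet`)."""
    path = Path(path)
    header: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line == "---":
                break
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise SweepFormatError(f"malformed header line {line!r}")
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        else:
            raise SweepFormatError("missing '---' separator before sweep data")
        for name in _REQUIRED_FIELDS:
            if name not in header:
                raise SweepFormatError(f"missing required header field {name!r}")
        n_sweeps = int(header["n_sweeps"])
        if n_sweeps < 1:
            raise SweepValidationError("n_sweeps >= 1 violated")
        rows = []
        for i, raw in enumerate(fh):
            if not raw.strip():
                continue
            rows.append(np.fromstring(raw, sep=","))
        if len(rows) != n_sweeps:
            raise SweepValidationError(
                f"header declares {n_sweeps} sweeps but file holds {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
            raise SweepValidationError(f"sweep {bad} has inconsistent length")
    fs = float(header["sampling_rate_Hz"])
    uv = (np.fromstring(header["uv_flash_s"], sep=",")
          if "uv_flash_s" in header else None)
    tv = (np.fromstring(header["test_voltages_mV"], sep=",")
          if "test_voltages_mV" in header else None)
    return SweepSet(
        cell_id=header["cell_id"],
        construct=header["construct"],
        sampling_rate_Hz=fs,
        protocol=_parse_protocol(header["protocol"]),
        sweeps=np.vstack(rows),
        unit=header["unit"],
        uv_flash_s=uv,
        test_voltages_mV=tv,
        seed=int(header["seed"]) if "seed" in header else None,
    )


# --------------------------------------------------------------------------
# analysis configuration

#: amplitudes (pA, at +60 mV) of the closed level and six sublevels used to
#: idealize single-channel records; adjacent open levels are spaced ~3/2.
DEFAULT_LADDER_PA = (0.0, 0.08, 0.13, 0.19, 0.29, 0.44, 0.66)


@dataclass
class AnalysisConfig:
    """Parameters shared by all analysis stages.

    ``level_amplitudes_pA`` is the subconductance ladder at +60 mV including
    the closed level 0; classification thresholds are midpoints of adjacent
    amplitudes.  ``min_dwell_s`` defaults to half the filter rise time,
    1/(2*filter_cutoff_Hz): events shorter than that are unresolvable.
    ``reversal_mV`` anchors slope-conductance fits (Nernst, 5/135 mM K+ at
    22 C, about -84 mV).  Exclusion bounds apply to whole-cell UV diaries.
    """

    level_amplitudes_pA: tuple[float, ...] = DEFAULT_LADDER_PA
    filter_cutoff_Hz: float = 200.0
    min_dwell_s: float | None = None
    histogram_bin_pA: float = 0.01
    reversal_mV: float = -84.0
    baseline_sweeps: int = 5
    max_peak_nA: float = 20.0
    min_peak_nA: float = 2.0
    min_peak_initial_ratio: float = 5.0
    tail_window_s: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        lad = tuple(float(x) for x in self.level_amplitudes_pA)
        if lad[0] != 0.0:
            raise ConfigurationError("level ladder must include 0 (closed) first")
        if any(b <= a for a, b in zip(lad, lad[1:])):
            raise ConfigurationError(
                f"level amplitudes must be strictly ascending, got {lad}")
        self.level_amplitudes_pA = lad
        if self.min_dwell_s is None:
            self.min_dwell_s = 1.0 / (2.0 * self.filter_cutoff_Hz)
        if self.baseline_sweeps < 1:
            raise ConfigurationError("baseline_sweeps >= 1 violated")

    @property
    def thresholds_pA(self) -> np.ndarray:
        """Classification boundaries: midpoints of adjacent ladder levels."""
        lad = np.asarray(self.level_amplitudes_pA)
        return (lad[:-1] + lad[1:]) / 2.0

    def ladder_at(self, voltage_mV: float, reference_mV: float = 60.0) -> np.ndarray:
        """Ladder scaled to ``voltage_mV`` along the ohmic driving force."""
        lad = np.asarray(self.level_amplitudes_pA)
        scale = (voltage_mV - self.reversal_mV) / (reference_mV - self.reversal_mV)
        return lad * scale

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


_CONFIG_FIELDS = {f: t for f, t in [
    ("level_amplitudes_pA", "ladder"), ("filter_cutoff_Hz", float),
    ("min_dwell_s", float), ("histogram_bin_pA", float), ("reversal_mV", float),
    ("baseline_sweeps", int), ("max_peak_nA", float), ("min_peak_nA", float),
    ("min_peak_initial_ratio", float), ("tail_window_s", float), ("seed", int),
]}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat ``key = value`` (or ``key: value``) configuration file.

    Unknown keys raise; absent keys take the documented defaults.  The
    ladder is a comma-separated list and must be strictly ascending.
    """
    kwargs = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sep = "=" if "=" in line else ":"
        if sep not in line:
            raise SweepFormatError(f"malformed config line {line!r}")
        key, _, value = line.partition(sep)
        key, value = key.strip(), value.strip()
        if key not in _CONFIG_FIELDS:
            raise ConfigurationError(f"unknown config key {key!r}")
        kind = _CONFIG_FIELDS[key]
        if kind == "ladder":
            kwargs[key] = tuple(float(x) for x in value.split(","))
        else:
            kwargs[key] = kind(value)
    return AnalysisConfig(**kwargs)
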