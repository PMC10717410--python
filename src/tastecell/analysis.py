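"""Electrophysiology analysis operators.

Turns simulated (or recorded) sweeps and traces into the quantities used to
characterize the channel and the model cell: I-V curves, reversal potentials,
inhibition ratios, action-potential metrics and firing cycle lengths.

Conventions: the I-V measurement window defaults to the last 10% of each step
(quasi-steady current); voltage derivatives use central differences on the
uniform sample grid with no smoothing (simulated traces are noise-free); AP
duration is measured between the threshold crossings around each peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .biophys import InvalidInputError
from .cell import SweepSet, Trace

__all__ = [
    "AnalysisError",
    "NoReversalError",
    "UndefinedRatioError",
    "IVCurve",
    "APMetrics",
    "TrainMetrics",
    "extract_iv",
    "estimate_reversal",
    "inhibition_ratio",
    "detect_aps",
    "cycle_length",
    "dvdt_extrema",
]


class AnalysisError(ValueError):
    """Analysis operator applied outside its domain."""


class NoReversalError(AnalysisError):
    """The I-V curve never changes sign, so no reversal can be interpolated."""


class UndefinedRatioError(AnalysisError):
    """Control current too small for a meaningful inhibition ratio."""


@dataclass(frozen=True)
class IVCurve:
    """Current-voltage relation sampled at the step potentials."""

    voltages: np.ndarray
    currents: np.ndarray
    measurement_window: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))
        object.__setattr__(self, "currents", np.asarray(self.currents, dtype=float))
        if self.voltages.size != self.currents.size:
            raise InvalidInputError("voltages and currents must have equal length")
        if self.voltages.size >= 2 and np.any(np.diff(self.voltages) <= 0):
            raise InvalidInputError("voltages must be strictly increasing")


@dataclass(frozen=True)
class APMetrics:
    """Per-action-potential measurements."""

    peak_v: float
    peak_t: float
    max_dvdt: float
    min_dvdt: float
    duration_at_threshold: float


@dataclass(frozen=True)
class TrainMetrics:
    """Spike-train summary: count and inter-peak cycle lengths (ms)."""

    n_spikes: int
    cycle_length_mean: float | None
    cycle_lengths: tuple = field(default_factory=tuple)


def _window_mean(trace: Trace, window: tuple) -> float:
    lo, hi = window
    if not hi > lo:
        raise AnalysisError(f"empty measurement window {window!r}")
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not np.any(mask):
        raise AnalysisError(
            f"window {window!r} ms lies outside the trace span "
            f"[{trace.times[0]}, {trace.times[-1]}] ms")
    return float(np.mean(trace.values[mask]))


def default_window(sweeps: SweepSet, fraction: float = 0.1) -> tuple:
    """Last ``fraction`` of the sweep duration — the quasi-steady segment."""
    t_end = float(sweeps.sweeps[0].times[-1])
    return ((1.0 - fraction) * t_end, t_end)


def extract_iv(sweeps: SweepSet, window: tuple | None = None) -> IVCurve:
    """Reduce a sweep family to an I-V curve: window-mean current per step.

    ``window`` is a (start_ms, end_ms) pair; by default the last 10% of each
    step, where the current is quasi-steady.
    """
    if window is None:
        window = default_window(sweeps)
    t0 = sweeps.sweeps[0].times
    for tr in sweeps.sweeps:
        if tr.times.size != t0.size or np.max(np.abs(tr.times - t0)) > 1e-9:
            raise AnalysisError("all sweeps must share one time grid")
    pairs = sorted(((tr.metadata["step_mV"], _window_mean(tr, window))
                    for tr in sweeps.sweeps), key=lambda p: p[0])
    v = np.array([p[0] for p in pairs])
    i = np.array([p[1] for p in pairs])
    return IVCurve(voltages=v, currents=i, measurement_window=tuple(window))


def estimate_reversal(iv: IVCurve) -> float:
    """Reversal potential (mV) by linear interpolation of the zero crossing.

    Scans the curve for adjacent points of opposite current sign and
    interpolates; with several crossings the one at the most negative
    voltage is returned (the physiological branch for an outward rectifier,
    whose small inward limb sits at hyperpolarized potentials).  A curve
    with no sign change raises :class:`NoReversalError` — with tiny inward
    currents the reversal is genuinely indeterminate.
    """
    v, i = iv.voltages, iv.currents
    exact = np.flatnonzero(i == 0.0)
    crossings = []
    for k in range(v.size - 1):
        if i[k] * i[k + 1] < 0:
            v_zero = v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])
            crossings.append(v_zero)
    if exact.size:
        crossings.extend(v[exact])
    if not crossings:
        raise NoReversalError("currents never change sign; reversal indeterminate")
    return float(min(crossings))


def inhibition_ratio(control: SweepSet, blocker: SweepSet, at_v: float = 60.0,
                     window: tuple | None = None) -> float:
    """Relative current remaining under a blocker: I_blocker / I_control at +60 mV.

    Both sweep sets must contain the step to ``at_v``; currents are
    window-means (default: last 10% of the step).  A control current below
    1 pA in magnitude raises :class:`UndefinedRatioError`.
    """
    if window is None:
        window = default_window(control)
    i_ctrl = _window_mean(control.sweep_at(at_v), window)
    i_blk = _window_mean(blocker.sweep_at(at_v), window)
    if abs(i_ctrl) < 1.0:
        raise UndefinedRatioError(
            f"control current at {at_v} mV is {i_ctrl:.3g} pA (<1 pA); ratio undefined")
    return i_blk / i_ctrl


def detect_aps(trace: Trace, threshold: float = 0.0, min_separation: float = 5.0) -> list:
    """Detect action potentials as local maxima above ``threshold`` (mV).

    Peaks closer than ``min_separation`` ms are merged, keeping the larger.
    Per-AP dV/dt extrema come from central differences over the half-open
    window between neighbouring peaks; duration is the time spent above the
    detection threshold around the peak.  Returns a (possibly empty) list of
    :class:`APMetrics` ordered by peak time.
    """
    if trace.kind != "voltage":
        raise AnalysisError("detect_aps expects a voltage trace")
    v = trace.values
    dt = trace.dt
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(v, height=threshold, distance=distance)
    if idx.size == 0:
        return []
    dvdt = np.gradient(v, trace.times)
    # AP windows: midpoints between adjacent peaks, trace edges outside
    bounds = [0] + [int((a + b) // 2) for a, b in zip(idx[:-1], idx[1:])] + [v.size - 1]
    out = []
    for j, p in enumerate(idx):
        lo, hi = bounds[j], bounds[j + 1]
        seg = slice(lo, hi + 1)
        above = v[seg] > threshold
        # threshold crossing times around this peak
        rel_peak = p - lo
        k_up = rel_peak
        while k_up > 0 and above[k_up - 1]:
            k_up -= 1
        k_dn = rel_peak
        while k_dn < above.size - 1 and above[k_dn + 1]:
            k_dn += 1
        duration = (k_dn - k_up) * dt
        out.append(APMetrics(
            peak_v=float(v[p]), peak_t=float(trace.times[p]),
            max_dvdt=float(np.max(dvdt[seg])), min_dvdt=float(np.min(dvdt[seg])),
            duration_at_threshold=float(duration)))
    return out


def cycle_length(aps: Sequence[APMetrics]) -> TrainMetrics:
    """Mean interval between successive AP peaks.

    All successive inter-peak intervals are averaged.  With fewer than two
    spikes the mean is absent (None), never zero.
    """
    times = np.array([ap.peak_t for ap in aps], dtype=float)
    if times.size < 2:
        return TrainMetrics(n_spikes=int(times.size), cycle_length_mean=None)
    diffs = np.diff(np.sort(times))
    return TrainMetrics(n_spikes=int(times.size),
                        cycle_length_mean=float(np.mean(diffs)),
                        cycle_lengths=tuple(float(d) for d in diffs))


def dvdt_extrema(trace: Trace, window: tuple | None = None) -> tuple:
    """(max, min) of dV/dt (mV/ms) by central differences, optionally windowed."""
    if trace.kind != "voltage":
        raise AnalysisError("dvdt_extrema expects a voltage trace")
    dvdt = np.gradient(trace.values, trace.times)
    if window is not None:
        lo, hi = window
        mask = (trace.times >= lo) & (trace.times <= hi)
        if not np.any(mask):
            raise AnalysisError(f"window {window!r} outside trace span")
        dvdt = dvdt[mask]
    return float(np.max(dvdt)), float(np.min(dvdt))
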