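"""Seeded synthetic-data generators.

Stand-ins for the study's raw data so every analysis stage can be exercised
against known ground truth: noisy voltage-clamp sweep families generated from
known channel parameters, current-clamp voltage traces with known spike
times, and expression tables with a planted set of filter-passing genes.

All generators are pure functions of their parameters and an explicit seed
(``numpy.random.default_rng``; no global state): the same call reproduces the
same output bitwise.  Ground truth travels with each fixture (planted ids,
true spike times, generating parameters) so fixtures are self-verifying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biophys import InvalidInputError
from .cell import (CellParams, SweepSet, Trace, VoltageClampProtocol,
                   simulate_voltage_clamp)
from .screen import ExpressionRecord

__all__ = [
    "NoiseSpec",
    "SpikeWaveform",
    "SyntheticExpressionTable",
    "gen_vc_sweeps",
    "gen_ap_trace",
    "gen_expression_table",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian noise: standard deviation (pA or mV) and seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidInputError(f"sd must be >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class SpikeWaveform:
    """Difference-of-exponentials spike template for fixture traces.

    amp * (exp(-t/tau_decay) - exp(-t/tau_rise)) normalized to peak at
    ``peak_v`` above baseline.  Defaults: 0.5 ms rise, 2 ms decay, peak at
    +50 mV — an artifact choice for detector fixtures only.
    """

    tau_rise: float = 0.5
    tau_decay: float = 2.0
    peak_v: float = 50.0


def gen_vc_sweeps(params: CellParams, protocol: VoltageClampProtocol,
                  noise: NoiseSpec = NoiseSpec()) -> SweepSet:
    """Voltage-clamp sweep family from known model parameters plus noise.

    With ``noise.sd = 0`` the output equals :func:`simulate_voltage_clamp`
    exactly; otherwise i.i.d. Gaussian noise of the given SD (pA) is added
    to every sample.  The generating parameters and noise spec are recorded
    in each sweep's metadata.
    """
    clean = simulate_voltage_clamp(params, protocol)
    rng = np.random.default_rng(noise.seed)
    sweeps = []
    for tr in clean:
        values = tr.values
        if noise.sd > 0:
            values = values + rng.normal(0.0, noise.sd, size=values.shape)
        meta = dict(tr.metadata)
        meta.update({"noise_sd_pA": noise.sd, "noise_seed": noise.seed,
                     "true_params": params.to_dict()})
        sweeps.append(Trace(times=tr.times, values=values, kind="current", metadata=meta))
    return SweepSet(sweeps=sweeps)


def gen_ap_trace(spike_times: Sequence[float], waveform: SpikeWaveform = SpikeWaveform(),
                 baseline: float = -70.0, noise: NoiseSpec = NoiseSpec(),
                 total_time: float = 500.0, sample_dt: float = 0.01) -> Trace:
    """Voltage trace with spike templates planted at known times.

    Spikes are difference-of-exponentials waveforms added to a flat
    baseline; overlapping templates superpose.  True spike times are stored
    in the trace metadata for self-verification.
    """
    n = int(round(total_time / sample_dt))
    times = np.linspace(0.0, total_time, n + 1)
    v = np.full(times.size, float(baseline))
    tr, td = waveform.tau_rise, waveform.tau_decay
    if not 0 < tr < td:
        raise InvalidInputError("need 0 < tau_rise < tau_decay")
    # normalize the template so its peak equals peak_v - baseline
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak_raw = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    amp = (waveform.peak_v - baseline) / peak_raw
    for t0 in spike_times:
        # shift by t_peak so the declared spike time is the waveform PEAK time
        tt = times - (float(t0) - t_peak)
        active = tt >= 0
        v[active] += amp * (np.exp(-tt[active] / td) - np.exp(-tt[active] / tr))
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        v = v + rng.normal(0.0, noise.sd, size=v.shape)
    return Trace(times=times, values=v, kind="voltage",
                 metadata={"true_spike_times_ms": [float(t) for t in spike_times],
                           "baseline_mV": baseline, "noise_sd_mV": noise.sd,
                           "noise_seed": noise.seed})


@dataclass(frozen=True)
class SyntheticExpressionTable:
    """Expression-table fixture with its planted ground truth."""

    records: tuple  # ExpressionRecord, shuffled order
    planted: tuple  # gene ids constructed to pass the screen
    min_cvp: float
    min_ratio: float
    seed: int


def gen_expression_table(n_genes: int, n_planted_pass: int, seed: int = 0,
                         min_cvp: float = 10.0, min_ratio: float = 3.0,
                         background_log_mean: float = 1.0,
                         background_log_sd: float = 1.5) -> SyntheticExpressionTable:
    """Expression table with exactly ``n_planted_pass`` filter-passing genes.

    Background genes draw log-normal CvP expression (natural-log mean/SD of
    the defaults give a right-skewed RPKM distribution spanning ~0.01-1000,
    the shape of real tissue RNA-seq) and a CvP/Epi ratio strictly below
    ``min_ratio``, so they fail the screen regardless of expression level.
    Planted genes draw CvP above ``min_cvp`` and ratios in [2*min_ratio,
    20*min_ratio], passing by construction.  Rows are shuffled; the planted
    ids are returned as ground truth.
    """
    if not 0 <= n_planted_pass <= n_genes:
        raise InvalidInputError("need 0 <= n_planted_pass <= n_genes")
    rng = np.random.default_rng(seed)
    n_bg = n_genes - n_planted_pass
    records = []
    for i in range(n_bg):
        cvp = float(rng.lognormal(background_log_mean, background_log_sd))
        ratio = float(rng.uniform(0.05, 0.95 * min_ratio))
        records.append(ExpressionRecord(f"bg{i:05d}", cvp, cvp / ratio))
    for i in range(n_planted_pass):
        cvp = float(min_cvp * rng.uniform(1.5, 50.0))
        ratio = float(rng.uniform(2.0 * min_ratio, 20.0 * min_ratio))
        records.append(ExpressionRecord(f"planted{i:05d}", cvp, cvp / ratio))
    order = rng.permutation(len(records))
    shuffled = tuple(records[k] for k in order)
    planted = tuple(r.gene_id for r in shuffled if r.gene_id.startswith("planted"))
    return SyntheticExpressionTable(records=shuffled, planted=planted,
                                    min_cvp=min_cvp, min_ratio=min_ratio, seed=seed)
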