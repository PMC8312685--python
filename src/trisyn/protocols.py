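"""Stimulus protocols, spike detection, firing rates and the study design.

The reference protocol pulses a depolarising 5 uA/cm^2 square current at
10 Hz into the presynaptic neuron over a 50 s window starting at 20 s; each
pulse is sized to elicit exactly one presynaptic spike in the disinhibited
(GAT-3 off) condition, yielding a 10 Hz presynaptic rate.  Firing rates are
reported as moving-window averages (1 s window, 10% overlap).

``run_paper_experiments`` executes the full factorial design - basal
astrocytic Glu in {1.5, 5, 10} mM crossed with the three feedback variants
(GAT-3 on with GABA_A receptors on both neurons, GAT-3 on with postsynaptic
GABA_A only, and GAT-3 off as control) - and summarises each run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import ModelConfig, default_config
from .simulator import SimResult, run

__all__ = [
    "Protocol",
    "FiringRateTrace",
    "pulsed_current",
    "detect_spikes",
    "firing_rate",
    "run_paper_experiments",
    "PAPER_VARIANTS",
    "GLU_AST_LEVELS",
]


@dataclass(frozen=True)
class Protocol:
    """Pulsed-current stimulus definition (amplitude in uA/cm^2, times in s)."""

    amplitude: float = 5.0        # applied current density (uA/cm^2)
    pulse_rate: float = 10.0      # pulses per second (Hz)
    pulse_width: float = 0.010    # square-pulse duration (s)
    window_start: float = 20.0    # stimulus window onset (s)
    window_duration: float = 50.0  # stimulus window length (s)
    total_duration: float = 90.0  # simulated time (s)
    threshold: float = 0.0        # spike detection threshold (mV)
    refractory: float = 2e-3      # spike detection refractory period (s)

    def validate(self) -> None:
        if self.pulse_rate <= 0 or self.pulse_width <= 0:
            raise ValueError("pulse rate and width must be positive")
        if self.pulse_width > 1.0 / self.pulse_rate:
            raise ValueError("pulse width exceeds the pulse period")
        if self.total_duration < 0:
            raise ValueError("total_duration must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def scaled(self, window_start: float, window_duration: float,
               total_duration: float) -> "Protocol":
        """Same stimulus with a shifted/shortened window (scaled protocols)."""
        return replace(self, window_start=window_start,
                       window_duration=window_duration,
                       total_duration=total_duration)


@dataclass
class FiringRateTrace:
    """Moving-window firing-rate estimate."""

    centers: np.ndarray   # window centres (s)
    rates: np.ndarray     # spikes per second within each window (Hz)
    window: float         # window length (s)
    overlap: float        # fractional overlap of consecutive windows


def pulsed_current(t, protocol: Protocol):
    """Applied current density (uA/cm^2) at time(s) ``t``.

    Square pulses at ``pulse_rate`` inside the stimulus window, zero outside;
    accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    in_window = (t >= protocol.window_start) & (
        t < protocol.window_start + protocol.window_duration)
    phase = np.mod(t - protocol.window_start, 1.0 / protocol.pulse_rate)
    out = np.where(in_window & (phase < protocol.pulse_width),
                   protocol.amplitude, 0.0)
    return float(out) if out.ndim == 0 else out


def detect_spikes(v_trace, time, threshold: float = 0.0,
                  refractory: float = 2e-3) -> np.ndarray:
    """Spike times from a membrane-potential trace on a uniform grid.

    A spike is an upward crossing of ``threshold`` (same units as the trace,
    mV for simulator output) separated from the previous spike by at least
    the refractory period.
    """
    v = np.asarray(v_trace, dtype=float)
    t = np.asarray(time, dtype=float)
    if v.shape != t.shape:
        raise ValueError("trace and time grid must have the same shape")
    if t.size > 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("detect_spikes requires a uniform time grid")
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    spikes = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= refractory:
            spikes.append(t[i])
            last = t[i]
    return np.array(spikes)


def firing_rate(spikes, window: float = 1.0, overlap: float = 0.1,
                span: tuple[float, float] | None = None) -> FiringRateTrace:
    """Moving-average firing rate: count/window with stride window*(1-overlap)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    spikes = np.asarray(spikes, dtype=float)
    if span is None:
        if spikes.size == 0:
            raise ValueError("an explicit span is required when there are no spikes")
        span = (float(spikes.min()), float(spikes.max()))
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("empty span")
    stride = window * (1.0 - overlap)
    starts = np.arange(t0, t1 - window + 1e-12, stride)
    if starts.size == 0:
        starts = np.array([t0])
    rates = np.array([np.count_nonzero((spikes >= s) & (spikes < s + window))
                      for s in starts]) / window
    return FiringRateTrace(centers=starts + window / 2.0, rates=rates,
                           window=window, overlap=overlap)


# the three feedback variants of the study: (gat3_enabled, gabaa_placement)
PAPER_VARIANTS = (
    (True, "both"),
    (True, "post_only"),
    (False, "none"),
)
GLU_AST_LEVELS = (1.5, 5.0, 10.0)


def _window_rate(spikes: np.ndarray, protocol: Protocol) -> float:
    """Mean firing rate (Hz) over the stimulus window, excluding the first
    1 s rate window (onset transient)."""
    t0 = protocol.window_start + 1.0
    t1 = protocol.window_start + protocol.window_duration
    if t1 <= t0:
        return 0.0
    n = np.count_nonzero((spikes >= t0) & (spikes < t1))
    return n / (t1 - t0)


def summarize_run(result: SimResult, protocol: Protocol) -> dict:
    """Scalar summary of one simulation (rates, peaks, E_GAT excursion)."""
    tr = result.traces
    in_win = (result.time >= protocol.window_start) & (
        result.time < protocol.window_start + protocol.window_duration)
    v_a_mv = result.config["v_ast"] * 1e3  # canonical config stores volts
    return {
        "pre_rate": _window_rate(result.spikes_pre, protocol),
        "post_rate": _window_rate(result.spikes_post, protocol),
        "pre_spikes": int(result.spikes_pre.size),
        "post_spikes": int(result.spikes_post.size),
        "peak_na_ast": float(tr["na_ast"].max()),
        "peak_glu_syn": float(tr["glu_syn"].max()),
        "peak_gaba_syn": float(tr["gaba_syn"].max()),
        "peak_k_syn": float(tr["k_syn"].max()),
        "min_k_ast": float(tr["k_ast"].min()),
        "min_egat_minus_va": float((tr["e_gat"] - v_a_mv)[in_win].min())
        if in_win.any() else float("nan"),
    }


def run_paper_experiments(config: ModelConfig | None = None,
                          protocol: Protocol | None = None,
                          glu_levels=GLU_AST_LEVELS,
                          variants=PAPER_VARIANTS,
                          keep_results: bool = True):
    """Run the factorial design and summarise each run.

    Returns ``(summary, results)``: a pandas DataFrame with one row per
    (basal Glu, variant) combination, and a dict mapping
    ``(glu_ast, gat3, placement)`` to the full :class:`SimResult`
    (empty when ``keep_results`` is False).
    """
    base = config or default_config()
    protocol = protocol or Protocol()
    protocol.validate()
    rows = []
    results = {}
    for glu_ast in glu_levels:
        for gat3, placement in variants:
            cfg = replace(base, glu_ast_basal=glu_ast, gat3_enabled=gat3,
                          gabaa_placement=placement)
            cfg.validate()
            result = run(cfg, protocol, on_error="partial")
            row = {"glu_ast": glu_ast, "gat3": gat3, "placement": placement,
                   "status": result.status, "fail_time": result.fail_time}
            row.update(summarize_run(result, protocol))
            rows.append(row)
            if keep_results:
                results[(glu_ast, gat3, placement)] = result
    return pd.DataFrame(rows), results
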