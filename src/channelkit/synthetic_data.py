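"""Seeded generators for every input the pipeline consumes.

Each generator returns its ground-truth parameters alongside the data (on
the trace's ``ground_truth`` attribute or as a separate record) so estimator
tests close the loop: generate with known truth, analyze, compare.

Defaults mirror the recording conditions the analyses assume: 10 kHz
sampling for whole-cell traces, 25 kHz for single-channel records, inward
currents negative, a first-order solution-exchange filter on concentration
steps, and additive Gaussian white noise (no 1/f or line noise — enough to
exercise estimator robustness without modelling rig specifics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_core import RateSet, ApplicationProtocol, simulate_occupancies, O
from .traces import CurrentTrace
from .dose_response import HillFit, hill_response
from .mg_block import WoodhullFit, woodhull_current
from .single_channel import ChannelEvent, EventList, filter_trace

__all__ = [
    "NoiseSpec", "generate_whole_cell_trace", "generate_synaptic_trace",
    "generate_single_channel_trace", "generate_iv_dataset", "generate_dose_response",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian white-noise specification (sd in pA)."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise(noise: NoiseSpec | None, n: int) -> np.ndarray:
    if noise is None or noise.sd == 0:
        return np.zeros(n)
    return noise.rng().normal(0.0, noise.sd, size=n)


def generate_whole_cell_trace(rates: RateSet, protocol: ApplicationProtocol,
                              scale: float = 100.0, sampling_rate: float = 10000.0,
                              noise: NoiseSpec | None = None) -> CurrentTrace:
    """Macroscopic current from the four-state scheme.

    The open-state occupancy is normalized to its maximum and scaled so the
    peak current is −``scale`` pA (inward); Gaussian noise is then added.
    Deterministic given the noise seed.
    """
    if not protocol.epochs:
        raise ValidationError("protocol must contain at least one epoch")
    if sampling_rate <= 0 or scale <= 0:
        raise ValidationError("sampling_rate and scale must be > 0")
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, protocol.t_end + dt / 2, dt)
    occ = simulate_occupancies(rates, protocol, t)
    p_o = occ.p_O
    peak = p_o.max()
    i = -scale * p_o / peak if peak > 0 else np.zeros_like(p_o)
    i = i + _noise(noise, len(t))
    return CurrentTrace(
        t=t, i=i, sampling_rate=sampling_rate, protocol=protocol,
        ground_truth={"rates": rates.to_dict(), "scale": scale,
                      "noise_sd": 0.0 if noise is None else noise.sd,
                      "seed": 0 if noise is None else noise.seed})


def generate_synaptic_trace(amp: float, tau_components, pulse_ms: float = 5.0,
                            sampling_rate: float = 10000.0,
                            noise: NoiseSpec | None = None,
                            rise_tau: float = 0.001,
                            duration: float | None = None,
                            baseline_s: float = 0.01) -> CurrentTrace:
    """Synaptic-like response to a brief agonist pulse.

    The rising phase follows the solution-exchange filter (time constant
    ``rise_tau``); the decay after the pulse is a sum of exponentials with
    the given (A_i, τ_i) weights, scaled so the peak current is −``amp`` pA.
    """
    comps = [(float(a), float(tau)) for a, tau in tau_components]
    if amp <= 0:
        raise ValidationError("amp must be > 0 (inward peak magnitude)")
    if any(a <= 0 or tau <= 0 for a, tau in comps):
        raise ValidationError("all amplitudes and time constants must be > 0")
    if rise_tau < 0 or pulse_ms <= 0:
        raise ValidationError("rise_tau >= 0 and pulse_ms > 0 required")
    pulse_s = pulse_ms * 1e-3
    tau_max = max(tau for _, tau in comps)
    if duration is None:
        duration = baseline_s + pulse_s + 7.0 * tau_max
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, duration + dt / 2, dt)
    y = np.zeros_like(t)
    t_on = baseline_s
    t_off = baseline_s + pulse_s
    rising = (t >= t_on) & (t < t_off)
    if rise_tau > 0:
        y[rising] = 1.0 - np.exp(-(t[rising] - t_on) / rise_tau)
        y_end = 1.0 - np.exp(-pulse_s / rise_tau)
    else:
        y[rising] = 1.0
        y_end = 1.0
    wsum = sum(a for a, _ in comps)
    after = t >= t_off
    decay = np.zeros(after.sum())
    for a, tau in comps:
        decay += (a / wsum) * np.exp(-(t[after] - t_off) / tau)
    y[after] = y_end * decay
    i = -amp * y + _noise(noise, len(t))
    protocol = ApplicationProtocol(
        epochs=[{"t_start": t_on, "t_end": t_off, "glutamate": 1000.0}],
        exchange_tau=rise_tau)
    return CurrentTrace(
        t=t, i=i, sampling_rate=sampling_rate, protocol=protocol,
        ground_truth={"amp": amp, "tau_components": comps, "pulse_ms": pulse_ms,
                      "rise_tau": rise_tau,
                      "noise_sd": 0.0 if noise is None else noise.sd})


def generate_single_channel_trace(amp: float, mean_open: float, mean_closed: float,
                                  duration: float, sampling_rate: float = 25000.0,
                                  filter_fc: float | None = None,
                                  noise: NoiseSpec | None = None) -> CurrentTrace:
    """Stochastic one-channel record with exponential dwell times.

    Dwell boundaries are quantized to the sampling grid before the trace is
    synthesized, and the quantized square-wave events are stored on
    ``events_truth`` so idealization can be compared sample-exactly.  If a
    corner frequency is given, a 4-pole Bessel-type low-pass is applied; the
    unfiltered idealized truth is kept either way.
    """
    if amp == 0:
        raise ValidationError("amp must be non-zero")
    if mean_open <= 0 or mean_closed <= 0 or duration <= 0:
        raise ValidationError("dwell means and duration must be > 0")
    rng = np.random.default_rng(0 if noise is None else noise.seed)
    warn_flag = duration < 10.0 * (mean_open + mean_closed) / 2.0

    dt = 1.0 / sampling_rate
    n = int(round(duration * sampling_rate))
    t = np.arange(n) * dt

    # alternate closed/open dwells, quantized to whole samples
    state_open = False
    idx = 0
    segs: list[tuple[int, int, bool]] = []  # (start_idx, n_samples, open)
    while idx < n:
        mean = mean_open if state_open else mean_closed
        dwell = rng.exponential(mean)
        k = int(round(dwell / dt))
        if k > 0:
            k = min(k, n - idx)
            if segs and segs[-1][2] == state_open:
                s0, sn, _ = segs.pop()
                segs.append((s0, sn + k, state_open))
            else:
                segs.append((idx, k, state_open))
            idx += k
        state_open = not state_open

    ideal = np.zeros(n)
    events = []
    for s0, sn, is_open in segs:
        if is_open:
            ideal[s0:s0 + sn] = amp
        events.append(ChannelEvent(t_start=s0 * dt, duration=sn * dt,
                                   state="open" if is_open else "closed",
                                   mean_amp=amp if is_open else float("nan")))
    truth = EventList(events=events, dead_time=0.0, baseline=0.0,
                      open_level=amp, total_time=n * dt)

    i = ideal + _noise(noise, n)
    trace = CurrentTrace(t=t, i=i, sampling_rate=sampling_rate,
                         events_truth=truth,
                         ground_truth={"amp": amp, "mean_open": mean_open,
                                       "mean_closed": mean_closed,
                                       "noise_sd": 0.0 if noise is None else noise.sd})
    if warn_flag:
        trace.warnings.append("record shorter than 10 mean dwell cycles")
    if filter_fc is not None:
        trace = filter_trace(trace, filter_fc)
    return trace


def generate_iv_dataset(fit_truth: WoodhullFit, voltages, mg: float,
                        noise_rel: float = 0.0, seed: int = 0):
    """Paired I–V tables without and with Mg²⁺.

    The Mg²⁺-free current is linear in (V − V_rev) with slope g0; the blocked
    current follows the Woodhull relation.  Relative Gaussian noise
    ``noise_rel`` multiplies each current.  Returns
    (table_no_mg, table_mg, truth_dict); tables have columns V_mV, I_pA.
    """
    v = np.asarray(voltages, dtype=float)
    if mg < 0 or noise_rel < 0:
        raise ValidationError("mg and noise_rel must be >= 0")
    if np.min(v) >= fit_truth.v_rev or np.max(v) <= fit_truth.v_rev:
        raise ValidationError("voltages must span the reversal potential")
    rng = np.random.default_rng(seed)
    i_free = fit_truth.g0 * (v - fit_truth.v_rev)
    i_mg = woodhull_current(v, mg, fit_truth)
    if noise_rel > 0:
        i_free = i_free * (1.0 + rng.normal(0.0, noise_rel, len(v)))
        i_mg = i_mg * (1.0 + rng.normal(0.0, noise_rel, len(v)))
    truth = {"g0": fit_truth.g0, "v_rev": fit_truth.v_rev, "a": fit_truth.a,
             "delta": fit_truth.delta, "mg": mg, "noise_rel": noise_rel, "seed": seed}
    return (pd.DataFrame({"V_mV": v, "I_pA": i_free}),
            pd.DataFrame({"V_mV": v, "I_pA": i_mg}), truth)


def generate_dose_response(truth: HillFit, concs, noise_rel: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Noisy samples from the forward Hill model.

    Responses carry multiplicative Gaussian noise of relative sd
    ``noise_rel``.  Returns a table (conc_uM, response) with the generating
    parameters attached as ``DataFrame.attrs['truth']``.
    """
    c = np.asarray(concs, dtype=float)
    if np.any(c <= 0):
        raise ValidationError("concentrations must be > 0")
    if noise_rel < 0:
        raise ValidationError("noise_rel must be >= 0")
    r = hill_response(c, truth)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        r = r * (1.0 + rng.normal(0.0, noise_rel, len(c)))
    df = pd.DataFrame({"conc_uM": c, "response": r})
    df.attrs["truth"] = {"ec50": truth.ec50, "h": truth.h, "i_max": truth.i_max,
                         "mode": truth.mode, "noise_rel": noise_rel, "seed": seed}
    return df
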