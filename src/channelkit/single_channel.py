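"""Single-channel idealization and amplitude analysis.

Openings and closures are detected by the half-amplitude threshold rule: a
transition is scored whenever the current crosses the midpoint between the
baseline and the open level.  Openings briefer than the dead time (446 μs,
2.5× the rise time of the 2 kHz recording filter) are censored — removed and
merged into the flanking closed time — since such events cannot be resolved
reliably after low-pass filtering.  The dead time is a fixed constant of the
analysis, not recomputed from the filter settings.

Amplitudes are summarized by a single Gaussian fitted to the open-event
sample distribution; sub-conductance levels are not modelled.  The
time-averaged open probability is total open time over record length (per
channel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import ValidationError, FitError
from .traces import CurrentTrace

__all__ = [
    "DEAD_TIME_S", "ChannelEvent", "EventList", "AmplitudeFit",
    "HalfAmplitudeIdealizer", "filter_trace", "idealize_half_threshold",
    "censor_events", "estimate_levels", "fit_amplitude_histogram",
    "single_channel_po",
]

#: minimum resolvable opening, s (2.5 × rise time of the 2 kHz analysis filter)
DEAD_TIME_S = 446e-6


@dataclass(frozen=True)
class ChannelEvent:
    t_start: float
    duration: float
    state: str  # "open" | "closed"
    mean_amp: float = float("nan")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass
class EventList:
    """Contiguous, alternating open/closed events covering ``total_time``."""

    events: list = field(default_factory=list)
    dead_time: float = DEAD_TIME_S
    baseline: float = 0.0
    open_level: float = float("nan")
    total_time: float = 0.0

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    @property
    def open_events(self) -> list:
        return [e for e in self.events if e.state == "open"]

    @property
    def open_time(self) -> float:
        return sum(e.duration for e in self.open_events)

    def validate(self):
        for a, b in zip(self.events, self.events[1:]):
            if abs(a.t_end - b.t_start) > 1e-9 or a.state == b.state:
                raise ValidationError("events must be contiguous and alternating")
        for e in self.open_events:
            if e.duration < self.dead_time - 1e-12:
                raise ValidationError("open event shorter than the dead time survived censoring")
        return self


@dataclass(frozen=True)
class AmplitudeFit:
    """Single-Gaussian open-level amplitude fit (signed mean, pA)."""

    mean_amp: float
    sd: float
    n_points: int
    degenerate: bool = False


def filter_trace(trace: CurrentTrace, fc: float, order: int = 4) -> CurrentTrace:
    """Bessel-type low-pass (digital bilinear realization, DC gain 1).

    ``fc`` is the −3 dB corner frequency in Hz and must be below Nyquist.
    """
    nyq = trace.sampling_rate / 2.0
    if not 0 < fc < nyq:
        raise ValidationError(f"fc must lie in (0, {nyq}) Hz, got {fc}")
    sos = signal.bessel(order, fc, btype="low", fs=trace.sampling_rate,
                        output="sos", norm="mag")
    # pad with the initial value so a step mid-record, not the onset, sets the transient
    x0 = trace.i[0]
    y = signal.sosfilt(sos, trace.i - x0) + x0
    return CurrentTrace(t=trace.t, i=y, sampling_rate=trace.sampling_rate,
                        protocol=trace.protocol, holding_potential=trace.holding_potential,
                        cell_id=trace.cell_id, construct=trace.construct,
                        ground_truth=trace.ground_truth, events_truth=trace.events_truth)


def estimate_levels(i: np.ndarray) -> tuple[float, float]:
    """Baseline and open level from the two-mode structure of the all-points
    amplitude distribution (2-means clustering; baseline = the more occupied
    cluster)."""
    i = np.asarray(i, dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(i)
    centers = km.cluster_centers_.ravel()
    counts = np.bincount(km.labels_, minlength=2)
    base_idx = int(np.argmax(counts))
    return float(centers[base_idx]), float(centers[1 - base_idx])


def censor_events(events: list, dead_time: float) -> list:
    """Remove openings briefer than ``dead_time`` and merge them into the
    flanking closed time.  Closed events are never removed, so censoring can
    only shrink the total open time."""
    kept: list[ChannelEvent] = []
    for e in events:
        if e.state == "open" and e.duration < dead_time - 1e-12:
            e = ChannelEvent(e.t_start, e.duration, "closed")
        if kept and kept[-1].state == e.state:
            prev = kept.pop()
            e = ChannelEvent(prev.t_start, prev.duration + e.duration, e.state,
                             prev.mean_amp if prev.state == "open" else float("nan"))
        kept.append(e)
    return kept


class HalfAmplitudeIdealizer(BaseEstimator):
    """Idealize a single-channel record by 50% threshold crossing.

    Parameters
    ----------
    baseline, open_level : float, optional
        Current levels in pA; estimated from the all-points histogram when
        not supplied.
    dead_time : float
        Openings briefer than this (s) are censored.
    fc : float, optional
        Apply a Bessel low-pass at this corner frequency before detection.

    Attributes
    ----------
    events_ : EventList
    """

    def __init__(self, baseline: float | None = None, open_level: float | None = None,
                 dead_time: float = DEAD_TIME_S, fc: float | None = None):
        self.baseline = baseline
        self.open_level = open_level
        self.dead_time = dead_time
        self.fc = fc

    def fit(self, trace: CurrentTrace, y=None):
        if self.fc is not None:
            trace = filter_trace(trace, self.fc)
        baseline, open_level = self.baseline, self.open_level
        if baseline is None or open_level is None:
            baseline, open_level = estimate_levels(trace.i)
        if open_level == baseline:
            raise ValidationError("open level must differ from baseline")

        x = trace.i
        direction = np.sign(open_level - baseline)
        thr = baseline + 0.5 * (open_level - baseline)
        is_open = (x - thr) * direction > 0

        # noise check against the 3-sigma separation precondition
        closed_samples = x[~is_open]
        if len(closed_samples) > 10:
            sd = float(np.std(closed_samples))
            if sd > 0 and abs(open_level - baseline) < 3 * sd:
                warnings.warn("open level within 3 SD of the baseline noise; "
                              "idealization may be unreliable")

        dt = trace.dt
        edges = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
        bounds = np.concatenate([[0], edges, [len(x)]])
        raw: list[ChannelEvent] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            state = "open" if is_open[a] else "closed"
            amp = float(np.mean(x[a:b])) if state == "open" else float("nan")
            raw.append(ChannelEvent(t_start=trace.t[0] + a * dt,
                                    duration=(b - a) * dt, state=state, mean_amp=amp))
        events = censor_events(raw, self.dead_time)
        self.events_ = EventList(events=events, dead_time=self.dead_time,
                                 baseline=float(baseline), open_level=float(open_level),
                                 total_time=len(x) * dt).validate()
        self.trace_ = trace
        return self


def idealize_half_threshold(trace: CurrentTrace, baseline: float | None = None,
                            open_level: float | None = None,
                            dead_time: float = DEAD_TIME_S) -> EventList:
    """50% threshold idealization with dead-time censoring; see
    :class:`HalfAmplitudeIdealizer`."""
    return HalfAmplitudeIdealizer(baseline=baseline, open_level=open_level,
                                  dead_time=dead_time).fit(trace).events_


def fit_amplitude_histogram(trace: CurrentTrace, events: EventList) -> AmplitudeFit:
    """Single Gaussian fitted to the open-event current samples.

    Returns the signed mean amplitude relative to the fitted baseline offset
    being zero (i.e., the absolute open level if baseline is 0 pA)."""
    opens = events.open_events
    if not opens:
        raise FitError("no open events survive dead-time censoring")
    samples = []
    for e in opens:
        m = (trace.t >= e.t_start - 1e-12) & (trace.t < e.t_end - 1e-12)
        samples.append(trace.i[m])
    samples = np.concatenate(samples)
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else 0.0
    if sd <= 0:
        return AmplitudeFit(mean_amp=mean, sd=0.0, n_points=len(samples), degenerate=True)
    return AmplitudeFit(mean_amp=mean, sd=sd, n_points=len(samples))


def single_channel_po(events: EventList, n_channels: int = 1) -> float:
    """Time-averaged open probability, percent:
    100 × open time / (record length × n_channels)."""
    if n_channels < 1:
        raise ValidationError("n_channels must be >= 1")
    if events.total_time <= 0:
        raise ValidationError("total_time must be > 0")
    return 100.0 * events.open_time / (events.total_time * n_channels)
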