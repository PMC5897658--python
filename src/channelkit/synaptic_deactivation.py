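"""Analysis of synaptic-like responses to brief (~5 ms) glutamate pulses.

The decay of current after agonist removal (deactivation) is fit with one or
two exponentials; for a double fit the reported time constant is the
amplitude-weighted mean

    τ_w = (A1·τ1 + A2·τ2) / (A1 + A2).

Steroid modulation of such responses is summarized by three factors:

* potentiation (%)  — relative increase of the peak amplitude,
* deceleration      — τ_steroid / τ_control,
* charge transfer   — (1 + potentiation/100) × deceleration,

the last being the fold change in the integral of the response (amplitude ×
time course).  Peaks entering the potentiation are the post-pulse extrema of
the fitted decay models, which is robust to single-sample noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

from .errors import ValidationError, FitError
from .traces import CurrentTrace

__all__ = [
    "DeactivationFit", "SynapticSummary", "DeactivationFitter",
    "fit_deactivation", "potentiation_percent", "deceleration",
    "charge_transfer_factor", "summarize_synaptic",
]


@dataclass(frozen=True)
class DeactivationFit:
    """Mono- or bi-exponential deactivation fit.

    Amplitudes are positive (pA); ``peak`` carries the sign of the response.
    ``tau_report`` is τ for one component and the weighted τ_w for two."""

    n_components: int
    a1: float
    tau1: float
    a2: float = 0.0
    tau2: float = float("nan")
    peak: float = float("nan")
    fit_rmse: float = float("nan")

    def __post_init__(self):
        if self.n_components not in (1, 2):
            raise ValidationError("n_components must be 1 or 2")
        if self.a1 <= 0 or self.tau1 <= 0:
            raise ValidationError("amplitudes and time constants must be > 0")
        if self.n_components == 2:
            if self.a2 <= 0 or not self.tau2 > 0:
                raise ValidationError("amplitudes and time constants must be > 0")
            if self.tau1 > self.tau2:
                raise ValidationError("components must be ordered tau1 <= tau2")

    @property
    def tau_report(self) -> float:
        if self.n_components == 1:
            return self.tau1
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / (self.a1 + self.a2)

    @property
    def tau_w(self) -> float:
        return self.tau_report

    def model(self, t_rel) -> np.ndarray:
        """Unsigned decay model evaluated at times after the fitted peak."""
        t_rel = np.asarray(t_rel, dtype=float)
        out = self.a1 * np.exp(-t_rel / self.tau1)
        if self.n_components == 2:
            out = out + self.a2 * np.exp(-t_rel / self.tau2)
        return out

    def area(self) -> float:
        """Analytic integral of the decay model from the peak, unsigned (pA·s)."""
        out = self.a1 * self.tau1
        if self.n_components == 2:
            out += self.a2 * self.tau2
        return out


@dataclass(frozen=True)
class SynapticSummary:
    """Steroid-effect summary for one control/steroid pair."""

    potentiation: float
    deceleration: float
    charge_transfer: float
    tau_control: float = float("nan")
    tau_steroid: float = float("nan")
    peak_control: float = float("nan")
    peak_steroid: float = float("nan")


def potentiation_percent(peak_steroid: float, peak_control: float) -> float:
    """Relative peak increase, percent: 100·(|peak_s| − |peak_c|)/|peak_c|."""
    if peak_control == 0:
        raise ValidationError("control peak must be non-zero")
    if peak_steroid * peak_control < 0:
        raise ValidationError("peaks must have the same sign")
    return 100.0 * (abs(peak_steroid) - abs(peak_control)) / abs(peak_control)


def deceleration(tau_steroid: float, tau_control: float) -> float:
    """Slowing of deactivation: τ_steroid / τ_control."""
    if tau_steroid <= 0 or tau_control <= 0:
        raise ValidationError("time constants must be > 0")
    return tau_steroid / tau_control


def charge_transfer_factor(potentiation: float, decel: float) -> float:
    """Fold change of the response integral: (1 + potentiation/100) × deceleration."""
    if decel <= 0:
        raise ValidationError("deceleration must be > 0")
    return (1.0 + potentiation / 100.0) * decel


class DeactivationFitter(BaseEstimator):
    """Exponential fit of the post-pulse decay of a synaptic-like response.

    Parameters
    ----------
    n_components : 1, 2 or "auto"
        "auto" keeps the second component only when it improves the residual
        by an F-test at ``alpha``.
    alpha : float
        F-test level for auto component selection.
    """

    def __init__(self, n_components="auto", alpha: float = 0.05):
        self.n_components = n_components
        self.alpha = alpha

    def _pulse_end(self, trace: CurrentTrace) -> float:
        if trace.protocol is not None:
            epoch = trace.protocol.first_epoch_where(glutamate=True)
            if epoch is not None:
                if (epoch.t_end - epoch.t_start) > 0.010 + 1e-9:
                    warnings.warn("agonist pulse longer than 10 ms; not synaptic-like")
                return float(epoch.t_end)
        # no protocol: start from the global extremum
        return float(trace.t[int(np.argmax(np.abs(trace.i)))])

    def fit(self, trace: CurrentTrace, y=None):
        if self.n_components not in (1, 2, "auto"):
            raise ValidationError("n_components must be 1, 2 or 'auto'")
        t_end = self._pulse_end(trace)
        m = trace.t >= t_end - 1e-12
        t = trace.t[m]
        i = trace.i[m]
        if len(t) < 10:
            raise ValidationError("decay window contains too few samples")
        # post-pulse extremum
        k0 = int(np.argmax(np.abs(i)))
        t = t[k0:] - t[k0]
        i = i[k0:]
        sign = -1.0 if i[0] < 0 else 1.0
        yda = sign * i  # positive-going decay
        peak0 = float(yda[0])
        if peak0 <= 0:
            raise FitError("no post-pulse response to fit")
        tail = float(np.mean(yda[-max(len(yda) // 20, 3):]))
        if tail > 0.9 * peak0:
            raise FitError("current does not decay after the pulse")

        # crude tau from the 1/e crossing
        below = np.nonzero(yda < peak0 / np.e)[0]
        tau0 = float(t[below[0]]) if len(below) else float(t[-1] / 3)
        tau0 = max(tau0, 2.0 / trace.sampling_rate)

        def single(tt, a, tau):
            return a * np.exp(-tt / tau)

        def double(tt, a1, tau1, a2, tau2):
            return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

        p1, _ = curve_fit(single, t, yda, p0=[peak0, tau0],
                          bounds=([1e-12, 1e-7], [np.inf, np.inf]), maxfev=20000)
        rss1 = float(np.sum((yda - single(t, *p1)) ** 2))

        choose_two = self.n_components == 2
        fit2 = None
        if self.n_components in (2, "auto"):
            try:
                p2, _ = curve_fit(double, t, yda,
                                  p0=[peak0 / 2, tau0 / 3, peak0 / 2, tau0 * 3],
                                  bounds=([1e-12, 1e-7, 1e-12, 1e-7],
                                          [np.inf] * 4), maxfev=40000)
                rss2 = float(np.sum((yda - double(t, *p2)) ** 2))
                fit2 = (p2, rss2)
            except RuntimeError:
                fit2 = None
            if self.n_components == "auto" and fit2 is not None:
                df2 = len(t) - 4
                if rss2 <= 0:
                    choose_two = rss2 < rss1
                else:
                    fstat = (rss1 - rss2) / 2.0 / (rss2 / df2)
                    choose_two = f_dist.sf(fstat, 2, df2) < self.alpha
            if self.n_components == 2 and fit2 is None:  # pragma: no cover
                raise FitError("double-exponential fit did not converge")

        if choose_two and fit2 is not None:
            (a1, tau1, a2, tau2), rss = fit2
            if tau1 > tau2:
                a1, tau1, a2, tau2 = a2, tau2, a1, tau1
            result = DeactivationFit(n_components=2, a1=a1, tau1=tau1, a2=a2, tau2=tau2,
                                     peak=sign * (a1 + a2),
                                     fit_rmse=float(np.sqrt(rss / len(t))))
        else:
            a, tau = p1
            result = DeactivationFit(n_components=1, a1=float(a), tau1=float(tau),
                                     peak=sign * float(a),
                                     fit_rmse=float(np.sqrt(rss1 / len(t))))
        if t[-1] < 3 * result.tau_report:
            warnings.warn("decay recorded for < 3 time constants; tau may be truncated")
        self.result_ = result
        return self

    @property
    def tau_report_(self): return self.result_.tau_report
    @property
    def peak_(self): return self.result_.peak


def fit_deactivation(trace: CurrentTrace, n_components="auto", **kwargs) -> DeactivationFit:
    """Mono/bi-exponential deactivation fit; see :class:`DeactivationFitter`."""
    return DeactivationFitter(n_components=n_components, **kwargs).fit(trace).result_


def summarize_synaptic(control_trace: CurrentTrace, steroid_trace: CurrentTrace,
                       n_components="auto") -> SynapticSummary:
    """Potentiation, deceleration and charge-transfer factors for a paired
    control/steroid synaptic-like recording from one cell."""
    fc = fit_deactivation(control_trace, n_components=n_components)
    fs = fit_deactivation(steroid_trace, n_components=n_components)
    pot = potentiation_percent(fs.peak, fc.peak)
    dec = deceleration(fs.tau_report, fc.tau_report)
    return SynapticSummary(
        potentiation=pot, deceleration=dec,
        charge_transfer=charge_transfer_factor(pot, dec),
        tau_control=fc.tau_report, tau_steroid=fs.tau_report,
        peak_control=fc.peak, peak_steroid=fs.peak)
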