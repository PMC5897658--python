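"""Step 1 of the open-probability procedure: desensitization analysis.

During a sustained saturating glutamate application the macroscopic current
declines from its peak I_P to a steady state I_SS with a single-exponential
onset of time constant τ_d.  The fractional desensitization and the onset /
recovery rate constants follow directly:

    D   = 1 − I_SS / I_P
    k_d = D / τ_d
    k_r = (1 − D) / τ_d

Window choices (peak search in the first 500 ms of the glutamate epoch after
1 ms median smoothing; steady state as the mean of the final 10%, at least
200 ms) are documented defaults of this package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import medfilt
from sklearn.base import BaseEstimator

from .errors import ValidationError, NoResponseError, ProtocolError, FitError
from .traces import CurrentTrace

__all__ = ["DesensFit", "DesensitizationAnalyzer", "analyze_desensitization", "desens_rates"]


@dataclass(frozen=True)
class DesensFit:
    """Peak/steady-state currents (pA, signed), desensitization fraction,
    onset time constant (s), and the derived rate constants (1/s).

    For non-desensitizing traces (D below the reporting floor) tau_d, k_d and
    k_r are NaN/0/NaN sentinels and ``non_desensitizing`` is set."""

    i_p: float
    i_ss: float
    tau_d: float
    d: float
    k_d: float
    k_r: float
    fit_rmse: float = float("nan")
    non_desensitizing: bool = False
    clipped: bool = False


def desens_rates(d: float, tau_d: float) -> tuple[float, float]:
    """(k_d, k_r) from the desensitization fraction and onset time constant."""
    if tau_d <= 0:
        raise ValidationError("tau_d must be > 0")
    if not 0 <= d < 1:
        raise ValidationError("D must lie in [0, 1)")
    return d / tau_d, (1.0 - d) / tau_d


class DesensitizationAnalyzer(BaseEstimator):
    """Measure I_P, I_SS, τ_d and the desensitization rate constants from a
    sustained-agonist trace.

    Parameters
    ----------
    peak_window_s : float
        Peak searched within this window after glutamate onset.
    smooth_ms : float
        Median-filter kernel applied before the extremum search.
    ss_fraction, ss_min_s : float
        Steady state averaged over the final fraction of the epoch, never
        less than ss_min_s.
    noise_floor_pa : float
        Cells with |I_P| below this are non-responders.
    non_desens_d : float
        Traces with D at or below this are reported as non-desensitizing and
        rate analysis is skipped.
    """

    def __init__(self, peak_window_s: float = 0.5, smooth_ms: float = 1.0,
                 ss_fraction: float = 0.1, ss_min_s: float = 0.2,
                 noise_floor_pa: float = 5.0, non_desens_d: float = 0.02):
        self.peak_window_s = peak_window_s
        self.smooth_ms = smooth_ms
        self.ss_fraction = ss_fraction
        self.ss_min_s = ss_min_s
        self.noise_floor_pa = noise_floor_pa
        self.non_desens_d = non_desens_d

    def _glutamate_window(self, trace: CurrentTrace) -> tuple[float, float]:
        if trace.protocol is not None:
            epoch = trace.protocol.first_epoch_where(glutamate=True)
            if epoch is None:
                raise ProtocolError("trace protocol contains no glutamate epoch")
            return max(epoch.t_start, trace.t[0]), min(epoch.t_end, trace.t[-1] + trace.dt)
        return float(trace.t[0]), float(trace.t[-1] + trace.dt)

    def fit(self, trace: CurrentTrace, y=None):
        t0, t1 = self._glutamate_window(trace)
        m = (trace.t >= t0 - 1e-12) & (trace.t < t1 - 1e-12)
        t = trace.t[m]
        i = trace.i[m]
        if len(t) < 10:
            raise ValidationError("glutamate epoch contains too few samples")

        kernel = max(1, int(round(self.smooth_ms * 1e-3 * trace.sampling_rate)))
        kernel += 1 - kernel % 2  # odd
        smooth = medfilt(i, kernel) if kernel > 1 else i

        peak_n = min(len(t), max(2, int(round(self.peak_window_s * trace.sampling_rate))))
        seg = smooth[:peak_n]
        peak_idx = int(np.argmax(np.abs(seg)))
        i_p = float(seg[peak_idx])
        if abs(i_p) < self.noise_floor_pa:
            raise NoResponseError(
                f"|I_P| = {abs(i_p):.2f} pA is below the {self.noise_floor_pa} pA response floor")

        ss_len = max(self.ss_fraction * (t[-1] - t[0]), self.ss_min_s)
        ss_n = min(len(t) - peak_idx - 1, max(2, int(round(ss_len * trace.sampling_rate))))
        i_ss = float(np.mean(i[-ss_n:]))

        ratio = i_ss / i_p
        clipped = False
        d = 1.0 - ratio
        if d < 0:
            warnings.warn("I_SS exceeds I_P; desensitization clipped at 0")
            d, clipped = 0.0, True

        if d <= self.non_desens_d:
            self.result_ = DesensFit(i_p=i_p, i_ss=i_ss, tau_d=math.nan, d=d,
                                     k_d=0.0, k_r=math.nan,
                                     non_desensitizing=True, clipped=clipped)
            return self

        # single exponential from the peak sample to epoch end, offset fixed at I_SS
        tf = t[peak_idx:] - t[peak_idx]
        yf = i[peak_idx:]
        amp0 = i_p - i_ss
        tau0 = max((t[-1] - t[peak_idx]) / 5.0, 2.0 / trace.sampling_rate)

        def model(tt, amp, tau):
            return i_ss + amp * np.exp(-tt / tau)

        try:
            popt, _ = curve_fit(model, tf, yf, p0=[amp0, tau0],
                                bounds=([-np.inf, 1e-6], [np.inf, np.inf]), maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"desensitization fit did not converge: {exc}") from exc
        tau_d = float(popt[1])
        rmse = float(np.sqrt(np.mean((yf - model(tf, *popt)) ** 2)))
        k_d, k_r = desens_rates(d, tau_d)
        self.result_ = DesensFit(i_p=i_p, i_ss=i_ss, tau_d=tau_d, d=d,
                                 k_d=k_d, k_r=k_r, fit_rmse=rmse, clipped=clipped)
        return self

    @property
    def i_p_(self): return self.result_.i_p
    @property
    def i_ss_(self): return self.result_.i_ss
    @property
    def tau_d_(self): return self.result_.tau_d
    @property
    def d_(self): return self.result_.d
    @property
    def k_d_(self): return self.result_.k_d
    @property
    def k_r_(self): return self.result_.k_r


def analyze_desensitization(trace: CurrentTrace, **params) -> DesensFit:
    """Peak, steady state, τ_d and rate constants of a sustained-agonist
    response; see :class:`DesensitizationAnalyzer`."""
    return DesensitizationAnalyzer(**params).fit(trace).result_
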