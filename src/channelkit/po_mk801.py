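"""Step 2 of the open-probability procedure: fitting the MK-801 block onset.

MK-801 binds only open channels, so the speed at which it extinguishes the
glutamate-evoked current reports the channel's open probability.  With k_d
and k_r fixed from the desensitization analysis, the closing rate k_c fixed
at 200 s⁻¹ and the blocking rate k_b at 25 μM⁻¹s⁻¹, the opening rate k_o is
the single free kinetic parameter; the reported quantity is

    P_o = 100 · k_o / (k_o + k_c)

because in the slow-block regime only the ratio k_o/(k_o + k_c) is
constrained by the data.  Block is treated as irreversible (k_u = 0) unless
the unblocking-rate variant is requested, in which case k_u is also free and
a residual plateau current under prolonged MK-801 reflects the
block/unblock balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .errors import ProtocolError, ValidationError
from .traces import CurrentTrace
from .desensitization import DesensFit, analyze_desensitization
from .model_core import (
    RateSet, open_probability, steady_state, _simulate_segment, O,
)

__all__ = ["PoFit", "OpenProbabilityFitter", "fit_po", "fit_po_with_unblock", "two_step_pipeline"]


@dataclass(frozen=True)
class PoFit:
    """MK-801 block-onset fit: opening rate (1/s), open probability
    (percent, = 100·k_o/(k_o+k_c)), unblocking rate (0 unless fitted), the
    current scale (pA) and fit diagnostics."""

    k_o: float
    p_o: float
    k_u: float
    scale: float
    residual_rmse: float
    converged: bool
    config_used: dict = field(default_factory=dict)
    warnings: tuple = ()


class OpenProbabilityFitter(BaseEstimator):
    """Fit the four-state model to the MK-801 inhibition onset.

    Parameters
    ----------
    k_c : float
        Closing rate, fixed (1/s).
    k_b : float
        MK-801 blocking rate, fixed (1/(μM·s)).
    ku_free : bool
        Also fit the unblocking rate k_u (used for variants where block is
        measurably reversible).
    scale_mode : {"free", "pinned"}
        Free current scale, or scale pinned so the model matches the pre-MK
        steady-state current.
    k_o_starts : tuple
        Multi-start grid for the opening rate, 1/s.

    Attributes
    ----------
    k_o_, p_o_, k_u_, scale_ : float
        Fitted parameters.
    converged_ : bool
    """

    def __init__(self, k_c: float = 200.0, k_b: float = 25.0, ku_free: bool = False,
                 scale_mode: str = "free", k_o_starts: tuple = (0.1, 1.0, 10.0, 100.0),
                 ku_max: float = 100.0, transient: str = "ode"):
        self.k_c = k_c
        self.k_b = k_b
        self.ku_free = ku_free
        self.scale_mode = scale_mode
        self.k_o_starts = k_o_starts
        self.ku_max = ku_max
        self.transient = transient

    # ------------------------------------------------------------------
    def _mk_epoch(self, trace: CurrentTrace):
        if trace.protocol is None:
            raise ProtocolError("trace has no application protocol")
        epoch = trace.protocol.first_epoch_where(mk801=True)
        if epoch is None:
            raise ProtocolError("protocol contains no MK-801 epoch")
        if epoch.glutamate <= 0:
            raise ProtocolError("MK-801 epoch must co-apply glutamate")
        return epoch

    def fit(self, trace: CurrentTrace, desens: DesensFit | None = None):
        if self.scale_mode not in ("free", "pinned"):
            raise ValidationError(f"unknown scale_mode {self.scale_mode!r}")
        epoch = self._mk_epoch(trace)
        if desens is None:
            desens = analyze_desensitization(trace)
        mk = epoch.mk801
        tau = trace.protocol.exchange_tau
        m = (trace.t >= epoch.t_start - 1e-12) & (trace.t < epoch.t_end - 1e-12)
        t_rel = trace.t[m] - epoch.t_start
        i_data = trace.i[m]
        if len(t_rel) < 20:
            raise ValidationError("MK-801 epoch contains too few samples")

        i_pre = abs(desens.i_ss)

        def p_open(k_o, k_u):
            rates = RateSet(k_d=desens.k_d, k_r=desens.k_r, k_o=k_o,
                            k_c=self.k_c, k_b=self.k_b, k_u=k_u)
            p0 = steady_state(rates, 0.0).p
            occ, _ = _simulate_segment(rates, 0.0, mk, tau, t_rel, p0,
                                       transient=self.transient)
            return occ[:, O]

        def scale_for(p_o_t, k_o):
            if self.scale_mode == "pinned":
                rates = RateSet(k_d=desens.k_d, k_r=desens.k_r, k_o=k_o, k_c=self.k_c)
                p_ss = steady_state(rates, 0.0).p_O
                return i_pre / max(p_ss, 1e-300)
            denom = float(p_o_t @ p_o_t)
            return float(-(p_o_t @ i_data) / denom) if denom > 0 else 0.0

        # coarse multi-start on k_o with the scale solved in closed form
        best = None
        ku0 = 1e-4 if self.ku_free else 0.0
        for k_o in self.k_o_starts:
            po_t = p_open(k_o, ku0)
            s = scale_for(po_t, k_o)
            cost = float(np.sum((-s * po_t - i_data) ** 2))
            if best is None or cost < best[1]:
                best = ((k_o, s), cost)
        (k_o0, s0), cost0 = best
        s0 = max(abs(s0), 1e-6)

        # refine by bounded NLS on log-parameterized rates
        def unpack(theta):
            k_o = np.exp(theta[0])
            if self.scale_mode == "free":
                s = np.exp(theta[1])
                k_u = np.exp(theta[2]) if self.ku_free else 0.0
            else:
                s = None
                k_u = np.exp(theta[1]) if self.ku_free else 0.0
            return k_o, s, k_u

        def resid(theta):
            k_o, s, k_u = unpack(theta)
            po_t = p_open(k_o, k_u)
            if s is None:
                s = scale_for(po_t, k_o)
            return -s * po_t - i_data

        theta0 = [np.log(k_o0)]
        lo, hi = [np.log(1e-4)], [np.log(1e4)]
        if self.scale_mode == "free":
            theta0.append(np.log(s0))
            lo.append(np.log(1e-9))
            hi.append(np.log(1e9))
        if self.ku_free:
            theta0.append(np.log(ku0))
            lo.append(np.log(1e-6))
            hi.append(np.log(self.ku_max))

        sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        k_o, s, k_u = unpack(sol.x)
        if s is None:
            s = scale_for(p_open(k_o, k_u), k_o)

        warns = []
        cost_init = float(np.sum(resid(np.asarray(theta0)) ** 2))
        converged = bool(sol.success) and sol.cost * 2 <= cost_init + 1e-12

        # a current that does not decay under MK-801 leaves k_o unidentified
        n5 = max(len(i_data) // 20, 5)
        head = float(np.mean(np.abs(i_data[:n5])))
        tail = float(np.mean(np.abs(i_data[-n5:])))
        noise = float(np.std(np.diff(i_data)) / np.sqrt(2)) if len(i_data) > 10 else 0.0
        if head - tail <= 3 * noise / np.sqrt(n5) + 1e-12:
            converged = False
            warns.append("current does not decay under MK-801; P_o unreliable")
        if self.ku_free and k_u > 0.9 * self.ku_max:
            warns.append("k_u at the upper search bound")
        for w in warns:
            warnings.warn(w)

        self.k_o_ = float(k_o)
        self.k_u_ = float(k_u)
        self.scale_ = float(s)
        self.p_o_ = open_probability(self.k_o_, self.k_c)
        self.residual_rmse_ = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
        self.converged_ = converged
        self.warnings_ = tuple(warns)
        return self

    @property
    def result_(self) -> PoFit:
        return PoFit(k_o=self.k_o_, p_o=self.p_o_, k_u=self.k_u_, scale=self.scale_,
                     residual_rmse=self.residual_rmse_, converged=self.converged_,
                     config_used={"k_c": self.k_c, "k_b": self.k_b,
                                  "scale_mode": self.scale_mode},
                     warnings=self.warnings_)


def fit_po(trace: CurrentTrace, desens: DesensFit | None = None,
           k_c: float = 200.0, k_b: float = 25.0, **kwargs) -> PoFit:
    """Irreversible-block P_o fit (k_u = 0); see :class:`OpenProbabilityFitter`."""
    return OpenProbabilityFitter(k_c=k_c, k_b=k_b, ku_free=False, **kwargs).fit(trace, desens).result_


def fit_po_with_unblock(trace: CurrentTrace, desens: DesensFit | None = None,
                        k_c: float = 200.0, k_b: float = 25.0, **kwargs) -> PoFit:
    """P_o fit with the MK-801 unblocking rate k_u also free."""
    return OpenProbabilityFitter(k_c=k_c, k_b=k_b, ku_free=True, **kwargs).fit(trace, desens).result_


def two_step_pipeline(control_trace: CurrentTrace, mk_trace: CurrentTrace | None = None,
                      ku_free: bool = False, k_c: float = 200.0, k_b: float = 25.0,
                      **kwargs) -> tuple[DesensFit, PoFit]:
    """Compose the two-step procedure on one cell.

    ``control_trace`` may be a combined protocol (glutamate epoch followed by
    a glutamate + MK-801 epoch); in that case ``mk_trace`` is omitted and the
    trace is split by epoch.
    """
    if control_trace.protocol is None:
        raise ProtocolError("control trace has no application protocol")
    ctrl_epoch = control_trace.protocol.first_epoch_where(glutamate=True, mk801=False)
    if ctrl_epoch is None:
        raise ProtocolError("missing glutamate-only control epoch")
    desens = analyze_desensitization(control_trace)
    target = mk_trace if mk_trace is not None else control_trace
    fitter = OpenProbabilityFitter(k_c=k_c, k_b=k_b, ku_free=ku_free, **kwargs)
    po = fitter.fit(target, desens).result_
    return desens, po
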