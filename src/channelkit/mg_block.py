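"""Woodhull-type fit of voltage-dependent Mg²⁺ block of NMDA-receptor I–V
relations.

The blocked current follows

    I(V) = a · g0 · (V − V_rev) / (a + [Mg²⁺] · e^{−bV}),    b = 2δF/(RT)

where ``a`` is the Mg²⁺ dissociation constant at 0 mV (so K_d(V) = a·e^{bV}),
δ the apparent electrical distance of the binding site from the outside of
the membrane, and g0 the unblocked conductance.  V is expressed in mV at all
interfaces and converted to volts inside the exponential; b is stored in V⁻¹.

Fitting is staged as in the experimental analysis: the Mg²⁺-free I–V is fit
by a line (giving g0 and V_rev, and normalizing both curves to unit slope),
then (a, δ) are fit to the normalized blocked curve with V_rev held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError, FitError

__all__ = [
    "FARADAY", "GAS_CONSTANT", "JUNCTION_POTENTIAL_MV",
    "WoodhullFit", "WoodhullBlockFit",
    "woodhull_current", "fit_woodhull", "relative_inhibition",
    "correct_junction_potential",
]

FARADAY = 96485.0        # C/mol
GAS_CONSTANT = 8.314     # J/(mol K)
#: measured liquid junction potential of the recording solutions, mV
JUNCTION_POTENTIAL_MV = 14.0


@dataclass(frozen=True)
class WoodhullFit:
    """Woodhull block parameters.

    g0 in normalized conductance units (1 after slope normalization) or nS;
    v_rev in mV; a in mM (= K_d at 0 mV); delta dimensionless in [0, 1]."""

    g0: float
    v_rev: float
    a: float
    delta: float
    T: float = 298.15
    se_a: float = float("nan")
    se_delta: float = float("nan")
    unreliable: bool = False

    def __post_init__(self):
        if self.a <= 0:
            raise ValidationError("a = K_d(0 mV) must be > 0")
        if not 0 <= self.delta <= 1:
            raise ValidationError("delta must lie in [0, 1]")
        if self.T <= 0:
            raise ValidationError("temperature must be > 0 K")

    @property
    def b(self) -> float:
        """Voltage-sensitivity b = 2δF/(RT), V⁻¹."""
        return 2.0 * self.delta * FARADAY / (GAS_CONSTANT * self.T)

    def k_d(self, v_mv) -> float:
        """Voltage-dependent dissociation constant K_d(V) = a·e^{bV}, mM."""
        return self.a * np.exp(self.b * np.asarray(v_mv, dtype=float) / 1000.0)


def woodhull_current(v_mv, mg: float, fit: WoodhullFit):
    """Blocked current at membrane potential ``v_mv`` (mV) and [Mg²⁺] (mM)."""
    if mg < 0:
        raise ValidationError("mg must be >= 0")
    v = np.asarray(v_mv, dtype=float)
    out = fit.a * fit.g0 * (v - fit.v_rev) / (fit.a + mg * np.exp(-fit.b * v / 1000.0))
    return float(out) if out.ndim == 0 else out


def relative_inhibition(v_mv: float, mg: float, fit: WoodhullFit) -> float:
    """Fractional block 1 − I_Mg/I_free at ``v_mv``; undefined at V_rev."""
    if mg < 0:
        raise ValidationError("mg must be >= 0")
    if abs(v_mv - fit.v_rev) < 1e-9:
        raise ValidationError("relative inhibition is undefined at the reversal potential")
    block = mg * np.exp(-fit.b * v_mv / 1000.0)
    return float(block / (fit.a + block))


def correct_junction_potential(v_hold_mv: float) -> float:
    """Holding potential corrected for the 14 mV liquid junction potential."""
    return v_hold_mv - JUNCTION_POTENTIAL_MV


def _as_iv(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        cols = {c.lower(): c for c in table.columns}
        vcol = next((cols[c] for c in ("v_mv", "v", "voltage_mv") if c in cols), table.columns[0])
        icol = next((cols[c] for c in ("i_pa", "i", "current_pa") if c in cols), table.columns[1])
        return table[vcol].to_numpy(float), table[icol].to_numpy(float)
    v, i = table
    return np.asarray(v, dtype=float), np.asarray(i, dtype=float)


class WoodhullBlockFit(RegressorMixin, BaseEstimator):
    """Scikit-learn regressor for voltage-dependent Mg²⁺ block.

    X has two columns, (V in mV, [Mg²⁺] in mM); y is current.  Rows with
    mg = 0 define the linear (unblocked) stage; rows with mg > 0 the block
    stage.  After fitting, ``predict`` evaluates the blocked I–V.
    """

    def __init__(self, T: float = 298.15, unreliable_block_floor: float = 0.05):
        self.T = T
        self.unreliable_block_floor = unreliable_block_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError("X must be (n, 2): columns V_mV and mg_mM")
        mg_vals = np.unique(X[X[:, 1] > 0, 1])
        if len(mg_vals) != 1:
            raise ValidationError("exactly one non-zero Mg²⁺ concentration is required")
        free = X[:, 1] == 0
        self._fit_tables((X[free, 0], y[free]), (X[~free, 0], y[~free]), float(mg_vals[0]))
        return self

    def _fit_tables(self, iv_no_mg, iv_mg, mg: float):
        if mg <= 0:
            raise ValidationError("mg must be > 0 for a block fit")
        v0, i0 = _as_iv(iv_no_mg)
        v1, i1 = _as_iv(iv_mg)
        if len(v0) < 3 or len(v1) < 3:
            raise ValidationError("need >= 3 I-V points in each table")
        if np.min(v1) >= 0 or np.max(v1) <= 0:
            import warnings
            warnings.warn("voltages do not span both sides of 0 mV; delta may be poorly constrained")

        # stage 1: linear fit of the unblocked I-V, then normalize to slope 1
        g0, icpt = np.polyfit(v0, i0, 1)
        if g0 == 0:
            raise FitError("unblocked I-V has zero slope")
        v_rev = -icpt / g0
        i1n = i1 / g0

        # stage 2: Eq for the blocked, normalized curve with V_rev fixed
        def model(v, a, delta):
            b = 2.0 * delta * FARADAY / (GAS_CONSTANT * self.T)
            return a * (v - v_rev) / (a + mg * np.exp(-b * v / 1000.0))

        try:
            popt, pcov = curve_fit(model, v1, i1n, p0=[max(mg, 1e-3), 0.5],
                                   bounds=([1e-9, 0.0], [1e6, 1.0]), maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"Woodhull fit did not converge: {exc}") from exc
        se = np.sqrt(np.diag(pcov))

        self.g0_ = float(g0)
        self.v_rev_ = float(v_rev)
        self.a_ = float(popt[0])
        self.delta_ = float(popt[1])
        self.se_a_ = float(se[0])
        self.se_delta_ = float(se[1])
        # block indistinguishable from the unblocked curve -> unreliable
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = 1.0 - i1n / ((v1 - v_rev))
        rel = rel[np.abs(v1 - v_rev) > 5.0]
        self.unreliable_ = bool(np.nanmax(np.abs(rel), initial=0.0) < self.unreliable_block_floor)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        fit = self.result_
        out = np.empty(len(X))
        for k, (v, mg) in enumerate(X):
            out[k] = woodhull_current(v, mg, fit)
        return out

    @property
    def result_(self) -> WoodhullFit:
        return WoodhullFit(g0=1.0, v_rev=self.v_rev_, a=self.a_, delta=self.delta_,
                           T=self.T, se_a=self.se_a_, se_delta=self.se_delta_,
                           unreliable=self.unreliable_)


def fit_woodhull(iv_no_mg, iv_mg, mg: float, T: float = 298.15) -> WoodhullFit:
    """Two-stage Woodhull fit from paired I–V tables (see module docstring).

    Tables are (V_mV, I) array pairs or DataFrames with columns V_mV, I_pA.
    The returned fit is on the slope-normalized scale (g0 = 1).
    """
    est = WoodhullBlockFit(T=T)
    est._fit_tables(iv_no_mg, iv_mg, mg)
    return est.result_
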