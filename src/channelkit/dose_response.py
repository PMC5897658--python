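"""Hill-equation fitting for agonist concentration–response and steroid
potentiation curves.

Agonist mode fits the normalized logistic

    I = 1 / (1 + (EC50/[agonist])^h)

so the curve passes through 0.5 at the EC50; potentiation mode adds a free
asymptote,

    I = I_max / (1 + (EC50/[steroid])^h).

Fitting is done on log-dose internally for conditioning; parameters are
reported on the linear scale, with log-scale values alongside (group
comparisons of potency are conventionally made on logEC50 / logHill).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError, FitError

__all__ = ["HillFit", "HillCurveFit", "hill_response", "fit_hill"]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters.

    ec50 in μM; h dimensionless; i_max is the potentiation asymptote in
    percent (fixed at 1 in normalized agonist mode)."""

    ec50: float
    h: float
    i_max: float = 1.0
    se_ec50: float = float("nan")
    se_h: float = float("nan")
    mode: str = "agonist"
    rmse: float = float("nan")

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValidationError("EC50 must be > 0")
        if self.h <= 0:
            raise ValidationError("Hill coefficient must be > 0")

    @property
    def log_ec50(self) -> float:
        return float(np.log10(self.ec50))

    @property
    def log_h(self) -> float:
        return float(np.log10(self.h))


def hill_response(conc, fit: HillFit):
    """Forward evaluation of the fitted curve at concentration(s) ``conc`` (μM)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValidationError("concentration must be > 0")
    out = fit.i_max / (1.0 + (fit.ec50 / conc) ** fit.h)
    return float(out) if out.ndim == 0 else out


class HillCurveFit(RegressorMixin, BaseEstimator):
    """Scikit-learn regressor for Hill dose–response curves.

    Parameters
    ----------
    mode : {"agonist", "potentiation"}
        Agonist mode fixes the asymptote at 1 (responses must be normalized
        to the saturating response); potentiation mode fits I_max freely.
    normalize : {None, "max"}
        In agonist mode, "max" divides responses by the response at the
        highest dose before fitting.

    Attributes
    ----------
    ec50_, h_, i_max_ : float
        Fitted parameters (μM, –, percent).
    se_ec50_, se_h_ : float
        Asymptotic standard errors from the fit covariance.
    """

    def __init__(self, mode: str = "agonist", normalize=None):
        self.mode = mode
        self.normalize = normalize

    # X is (n,) or (n, 1) concentrations in μM
    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValidationError("X must have a single concentration column")
            X = X[:, 0]
        if np.any(X <= 0):
            raise ValidationError("doses must be > 0")
        return X

    def fit(self, X, y):
        if self.mode not in ("agonist", "potentiation"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        doses = self._check_X(X)
        resp = np.asarray(y, dtype=float)
        if resp.shape != doses.shape:
            raise ValidationError("doses and responses must have equal length")
        if len(np.unique(doses)) < 3:
            raise ValidationError("need >= 3 distinct doses")
        if np.ptp(resp) <= 1e-12 * max(1.0, np.max(np.abs(resp))):
            raise FitError("no dose dependence: all responses equal")
        order = np.argsort(doses)
        doses, resp = doses[order], resp[order]
        if self.mode == "agonist" and self.normalize == "max":
            resp = resp / resp[-1]

        span = np.max(doses) / np.min(doses)
        if len(doses) < 4 or span < 30:
            warnings.warn("fewer than 4 doses or narrow dose span: EC50 may be poorly constrained")

        logx = np.log(doses)
        top0 = 1.0 if self.mode == "agonist" else float(np.max(resp)) * 1.2
        half = 0.5 * top0
        # dose where the response crosses half of the asymptote guess
        idx = int(np.searchsorted(resp, half)) if resp[-1] > resp[0] else len(resp) // 2
        idx = min(max(idx, 1), len(doses) - 1)
        ec50_0 = np.sqrt(doses[idx - 1] * doses[idx])

        if self.mode == "agonist":
            def model(lx, log_ec50, h):
                return 1.0 / (1.0 + np.exp(h * (log_ec50 - lx)))
            p0 = [np.log(ec50_0), 1.3]
            bounds = ([np.log(doses.min()) - 12, 0.05], [np.log(doses.max()) + 12, 10.0])
        else:
            def model(lx, log_ec50, h, i_max):
                return i_max / (1.0 + np.exp(h * (log_ec50 - lx)))
            p0 = [np.log(ec50_0), 1.3, top0]
            bounds = ([np.log(doses.min()) - 12, 0.05, 0.0],
                      [np.log(doses.max()) + 12, 10.0, 100 * top0 + 1.0])

        try:
            popt, pcov = curve_fit(model, logx, resp, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"Hill fit did not converge: {exc}") from exc

        pred = model(logx, *popt)
        resid = resp - pred
        rms = float(np.sqrt(np.mean(resid**2)))
        # flag non-monotonicity beyond the residual noise
        drops = np.diff(resp)
        if np.any(drops < -max(3 * rms, 1e-9)):
            warnings.warn("responses are non-monotonic beyond noise")

        se = np.sqrt(np.diag(pcov))
        self.ec50_ = float(np.exp(popt[0]))
        self.h_ = float(popt[1])
        self.i_max_ = float(popt[2]) if self.mode == "potentiation" else 1.0
        self.se_ec50_ = float(self.ec50_ * se[0])  # delta method from log scale
        self.se_h_ = float(se[1])
        self.rmse_ = rms
        self.n_points_ = len(doses)
        return self

    def predict(self, X):
        doses = self._check_X(X)
        return hill_response(doses, self.result_)

    @property
    def result_(self) -> HillFit:
        return HillFit(ec50=self.ec50_, h=self.h_, i_max=self.i_max_,
                       se_ec50=self.se_ec50_, se_h=self.se_h_,
                       mode=self.mode, rmse=self.rmse_)


def fit_hill(doses, responses, mode: str = "agonist", **kwargs) -> HillFit:
    """Least-squares Hill fit; see :class:`HillCurveFit`."""
    return HillCurveFit(mode=mode, **kwargs).fit(doses, responses).result_
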