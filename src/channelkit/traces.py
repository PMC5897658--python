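"""The in-memory current-trace container shared by all analyses.

Conventions fixed package-wide: time in s, current in pA (inward currents
negative), potential in mV, concentrations in μM (Mg²⁺ in mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .model_core import ApplicationProtocol

__all__ = ["CurrentTrace"]


@dataclass
class CurrentTrace:
    """Uniformly sampled current record with protocol annotations.

    Attributes
    ----------
    t : ndarray
        Sample times, s, uniform and strictly increasing.
    i : ndarray
        Current, pA; inward currents are negative.
    sampling_rate : float
        Hz; must match the time column.
    protocol : ApplicationProtocol, optional
        Which solutions are present when.
    holding_potential : float, optional
        mV (after junction-potential correction where applicable).
    ground_truth : dict, optional
        Generating parameters, present on synthetic traces only.
    events_truth : optional
        Idealized ground-truth event list for synthetic single-channel
        records (see :mod:`channelkit.single_channel`).
    """

    t: np.ndarray
    i: np.ndarray
    sampling_rate: float
    protocol: ApplicationProtocol | None = None
    holding_potential: float | None = None
    cell_id: str | None = None
    construct: str | None = None
    ground_truth: dict | None = None
    events_truth: object | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValidationError("time and current must be 1-d arrays of equal length")
        if len(self.t) < 2:
            raise ValidationError("trace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * dt[0] + 1e-12:
            raise ValidationError("time must be uniformly sampled")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if abs(dt[0] - 1.0 / self.sampling_rate) > 1e-6 * dt[0]:
            raise ValidationError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with time step {dt[0]} s")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, t_start: float, t_end: float) -> "CurrentTrace":
        """Sub-trace covering [t_start, t_end)."""
        m = (self.t >= t_start - 1e-12) & (self.t < t_end - 1e-12)
        if m.sum() < 2:
            raise ValidationError(f"window [{t_start}, {t_end}) contains < 2 samples")
        return CurrentTrace(
            t=self.t[m], i=self.i[m], sampling_rate=self.sampling_rate,
            protocol=self.protocol, holding_potential=self.holding_potential,
            cell_id=self.cell_id, construct=self.construct,
            ground_truth=self.ground_truth)
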