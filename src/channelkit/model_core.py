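"""Four-state kinetic scheme for NMDA-receptor gating and MK-801 block.

The receptor is modelled as a linear chain of doubly liganded states

    D  <-k_r--k_d->  R  <-k_o--k_c->  O  <-k_b[MK]--k_u->  B

where D is desensitized, R closed (resting), O open, and B blocked by the
open-channel blocker MK-801.  Agonist binding steps are omitted: at a
saturating glutamate concentration the receptor is essentially always
doubly liganded, so occupancy moves only between these four states.  The
master equation is linear, dp/dt = A(c)·p, with the only time dependence
entering through the effective MK-801 concentration c(t), which relaxes
first-order toward each epoch's nominal value with the solution-exchange
time constant.

Because the generator is constant within (filtered) sub-intervals, the
occupancies are propagated exactly with the matrix exponential /
eigendecomposition of the constant-coefficient generator; an adaptive ODE
integrator is available as an independent cross-check and as a fast path
inside iterative fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

from .errors import ValidationError, DegenerateSchemeError

__all__ = [
    "RateSet",
    "Epoch",
    "ApplicationProtocol",
    "StateOccupancy",
    "SteadyState",
    "generator_matrix",
    "simulate_occupancies",
    "steady_state",
    "open_probability",
    "mendelian_activity",
    "D", "R", "O", "B",
]

# state indices
D, R, O, B = 0, 1, 2, 3
STATE_NAMES = ("D", "R", "O", "B")

#: room temperature used for any thermodynamic constant, K
ROOM_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class RateSet:
    """Rate constants of the D⇌R⇌O⇌B scheme.

    Parameters
    ----------
    k_d : float
        Desensitization rate R→D, 1/s.
    k_r : float
        Resensitization rate D→R, 1/s.
    k_o : float
        Channel opening rate R→O, 1/s.
    k_c : float
        Channel closing rate O→R, 1/s (fixed at 200 s⁻¹ in the
        open-probability procedure).
    k_b : float
        MK-801 blocking rate O→B, 1/(μM·s).
    k_u : float
        MK-801 unblocking rate B→O, 1/s; 0 encodes irreversible block.
    """

    k_d: float = 0.0
    k_r: float = 0.0
    k_o: float = 0.0
    k_c: float = 200.0
    k_b: float = 25.0
    k_u: float = 0.0

    def __post_init__(self):
        for name in ("k_d", "k_r", "k_o", "k_c", "k_b", "k_u"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"rate {name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RateSet":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class Epoch:
    """One application epoch: which solutions are present in [t_start, t_end).

    Concentrations are μM except Mg²⁺ (mM)."""

    t_start: float
    t_end: float
    glutamate: float = 0.0
    glycine: float = 0.0
    mk801: float = 0.0
    mg: float = 0.0
    steroid: float = 0.0

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValidationError(f"epoch must have t_end > t_start, got [{self.t_start}, {self.t_end}]")
        for name in ("glutamate", "glycine", "mk801", "mg", "steroid"):
            if getattr(self, name) < 0:
                raise ValidationError(f"concentration {name} must be >= 0")


@dataclass
class ApplicationProtocol:
    """Ordered, non-overlapping application epochs plus the solution-exchange
    time constant (s); exchange_tau = 0 gives instantaneous concentration steps."""

    epochs: list = field(default_factory=list)
    exchange_tau: float = 0.012

    def __post_init__(self):
        self.epochs = [e if isinstance(e, Epoch) else Epoch(**e) for e in self.epochs]
        if self.exchange_tau < 0:
            raise ValidationError("exchange_tau must be >= 0")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.t_start < a.t_end:
                raise ValidationError("epochs must be ordered and non-overlapping")

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_end if self.epochs else 0.0

    def glutamate_onset(self) -> float | None:
        """Time of the first epoch containing glutamate, or None."""
        for e in self.epochs:
            if e.glutamate > 0:
                return e.t_start
        return None

    def first_epoch_where(self, **conditions) -> Epoch | None:
        """First epoch whose listed concentrations are all > 0 (value True)
        or == 0 (value False)."""
        for e in self.epochs:
            ok = True
            for name, want in conditions.items():
                present = getattr(e, name) > 0
                if present != bool(want):
                    ok = False
                    break
            if ok:
                return e
        return None

    def to_dict(self) -> dict:
        return {"epochs": [asdict(e) for e in self.epochs], "exchange_tau": self.exchange_tau}

    @classmethod
    def from_dict(cls, d: dict) -> "ApplicationProtocol":
        return cls(epochs=d.get("epochs", []), exchange_tau=d.get("exchange_tau", 0.012))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ApplicationProtocol":
        return cls.from_dict(json.loads(s))


@dataclass
class StateOccupancy:
    """State occupancies on a time grid; each row of ``p`` sums to 1."""

    t: np.ndarray
    p_D: np.ndarray
    p_R: np.ndarray
    p_O: np.ndarray
    p_B: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return np.stack([self.p_D, self.p_R, self.p_O, self.p_B], axis=1)

    @classmethod
    def from_matrix(cls, t: np.ndarray, p: np.ndarray) -> "StateOccupancy":
        return cls(t=t, p_D=p[:, D], p_R=p[:, R], p_O=p[:, O], p_B=p[:, B])


@dataclass
class SteadyState:
    """Stationary occupancies; ``absorbing`` flags the irreversible-block case
    where all probability ends in B."""

    p: np.ndarray
    absorbing: bool = False

    @property
    def p_O(self) -> float:
        return float(self.p[O])


def generator_matrix(rates: RateSet, mk801: float) -> np.ndarray:
    """Generator A of dp/dt = A·p for the chain at MK-801 concentration
    ``mk801`` (μM).  Columns sum to zero."""
    kbc = rates.k_b * mk801
    return np.array(
        [
            [-rates.k_r, rates.k_d, 0.0, 0.0],
            [rates.k_r, -(rates.k_d + rates.k_o), rates.k_c, 0.0],
            [0.0, rates.k_o, -(rates.k_c + kbc), rates.k_u],
            [0.0, 0.0, kbc, -rates.k_u],
        ]
    )


def open_probability(k_o: float, k_c: float) -> float:
    """Microscopic open probability, percent: 100·k_o/(k_o + k_c)."""
    if k_c <= 0:
        raise ValidationError(f"k_c must be > 0, got {k_c}")
    if k_o < 0:
        raise ValidationError(f"k_o must be >= 0, got {k_o}")
    return 100.0 * k_o / (k_o + k_c)


def mendelian_activity(po_wt: float, po_mut: float, mode: str) -> float:
    """Whole-population NMDAR activity of a heterozygous carrier relative to
    an all-wild-type population, percent.

    GluN2B-containing receptors carry two GluN2B subunits, so a heterozygote
    expresses 25% wild-type-only, 50% mixed, and 25% mutant-only receptors.
    Mixed receptors take the wild-type P_o (``recessive``), the mean of the
    two (``independent``), or the mutant P_o (``dominant``).
    """
    for name, v in (("po_wt", po_wt), ("po_mut", po_mut)):
        if not 0 <= v <= 100:
            raise ValidationError(f"{name} must lie in [0, 100], got {v}")
    if po_wt == 0:
        raise ValidationError("po_wt must be > 0 to define relative activity")
    mixed = {
        "recessive": po_wt,
        "independent": 0.5 * (po_wt + po_mut),
        "dominant": po_mut,
    }
    if mode not in mixed:
        raise ValidationError(f"unknown mode {mode!r}; expected recessive|independent|dominant")
    total = 0.25 * po_wt + 0.5 * mixed[mode] + 0.25 * po_mut
    return 100.0 * total / po_wt


def steady_state(rates: RateSet, mk801: float = 0.0) -> SteadyState:
    """Stationary occupancies of the scheme at a fixed MK-801 concentration.

    With mk801 = 0 the three-state sub-scheme D⇌R⇌O gives, by detailed
    balance, p_O = (k_o/k_c) / (1 + k_d/k_r + k_o/k_c).  With mk801 > 0 and
    k_u = 0 the blocked state is absorbing and the returned distribution is
    the point mass on B, flagged.
    """
    if mk801 < 0:
        raise ValidationError("mk801 must be >= 0")
    if rates.k_c == 0 or (rates.k_d > 0 and rates.k_r == 0):
        raise DegenerateSchemeError("scheme has no stationary distribution with k_c = 0 or k_r = 0")
    if mk801 > 0 and rates.k_u == 0:
        p = np.zeros(4)
        p[B] = 1.0
        return SteadyState(p=p, absorbing=True)
    # detailed balance along the chain
    w_R = 1.0
    w_D = rates.k_d / rates.k_r if rates.k_d > 0 else 0.0
    w_O = rates.k_o / rates.k_c
    w_B = w_O * rates.k_b * mk801 / rates.k_u if mk801 > 0 else 0.0
    w = np.array([w_D, w_R, w_O, w_B])
    return SteadyState(p=w / w.sum(), absorbing=False)


# ---------------------------------------------------------------------------
# propagation

_EIG_COND_MAX = 1e10


def _propagate_const(A: np.ndarray, p0: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Occupancies at relative times ``ts`` (>= 0) under a constant generator.

    Uses the eigendecomposition p(t) = V e^{Λt} V⁻¹ p0, with a stepwise
    matrix-exponential fallback when V is ill-conditioned.
    """
    w, V = np.linalg.eig(A)
    ok = np.isfinite(np.linalg.cond(V)) and np.linalg.cond(V) < _EIG_COND_MAX
    if ok:
        coeff = np.linalg.solve(V, p0.astype(complex))
        out = (np.exp(np.outer(ts, w)) * coeff) @ V.T
        out = np.ascontiguousarray(out.real)
    else:  # pragma: no cover - degenerate rate sets only
        out = np.empty((len(ts), 4))
        order = np.argsort(ts)
        p = p0.copy()
        t_prev = 0.0
        for idx in order:
            dt = ts[idx] - t_prev
            if dt > 0:
                p = expm(A * dt) @ p
                t_prev = ts[idx]
            out[idx] = p
    return np.clip(out, 0.0, 1.0)


def _mk_profile(c0: float, c_target: float, tau: float):
    """Effective MK-801 concentration c(t) relaxing from c0 to c_target."""

    def c(t):
        return c_target + (c0 - c_target) * np.exp(-t / tau)

    return c


def _mk_step_average(c0, c_target, tau, t0, t1):
    """Exact time average of the relaxing concentration over [t0, t1]."""
    dt = t1 - t0
    decay = np.exp(-t0 / tau) - np.exp(-t1 / tau)
    return c_target + (c0 - c_target) * tau * decay / dt


def _transient_expm(rates, c0, c_target, tau, t_rel, p0):
    """Exact-propagator integration through a concentration transient.

    One matrix-exponential step per grid interval, using the exact average
    concentration over the interval (the generator is affine in c)."""
    out = np.empty((len(t_rel), 4))
    p = p0.copy()
    t_prev = 0.0
    for i, t in enumerate(t_rel):
        if t > t_prev:
            cbar = _mk_step_average(c0, c_target, tau, t_prev, t)
            p = expm(generator_matrix(rates, cbar) * (t - t_prev)) @ p
            t_prev = t
        out[i] = p
    return np.clip(out, 0.0, 1.0)


def _transient_ode(rates, c0, c_target, tau, t_rel, p0):
    """Adaptive-ODE integration of the transient (fast path for fits)."""
    c = _mk_profile(c0, c_target, tau)
    A0 = generator_matrix(rates, 0.0)
    A1 = generator_matrix(rates, 1.0) - A0

    def rhs(t, p):
        return (A0 + c(t) * A1) @ p

    if t_rel[-1] <= 0:
        return np.tile(p0, (len(t_rel), 1))
    t_span = (0.0, float(t_rel[-1]))
    sol = solve_ivp(rhs, t_span, p0, t_eval=t_rel, method="LSODA",
                    rtol=1e-9, atol=1e-12)
    return np.clip(sol.y.T, 0.0, 1.0)


#: effective-concentration convergence horizon, in multiples of exchange_tau
_TRANSIENT_HORIZON = 21.0


def _simulate_segment(rates, c0, c_target, tau, t_rel, p0, transient="expm"):
    """Occupancies at relative times t_rel (uniform, t_rel[0] >= 0) for one
    epoch whose effective MK-801 relaxes from c0 to c_target.

    Returns (occupancies, c_end)."""
    t_rel = np.asarray(t_rel, dtype=float)
    n = len(t_rel)
    out = np.empty((n, 4))
    if tau == 0 or c0 == c_target:
        A = generator_matrix(rates, c_target)
        out[:] = _propagate_const(A, p0, t_rel)
        return out, c_target
    t_tr = _TRANSIENT_HORIZON * tau
    in_tr = t_rel < t_tr
    integrate = _transient_expm if transient == "expm" else _transient_ode
    p_at = p0
    t_at = 0.0
    if in_tr.any():
        tt = t_rel[in_tr]
        # include first point even if t_rel[0] == 0
        out[in_tr] = integrate(rates, c0, c_target, tau, tt, p0)
        p_at = out[in_tr][-1]
        t_at = tt[-1]
    if (~in_tr).any():
        # bridge exactly to the first post-transient sample, then go constant
        t_rest = t_rel[~in_tr]
        dt_bridge = t_rest[0] - t_at
        if dt_bridge > 0:
            cbar = _mk_step_average(c0, c_target, tau, t_at, t_rest[0])
            p_at = expm(generator_matrix(rates, cbar) * dt_bridge) @ p_at
        A = generator_matrix(rates, c_target)
        out[~in_tr] = _propagate_const(A, p_at, t_rest - t_rest[0])
    c_end = c_target + (c0 - c_target) * np.exp(-t_rel[-1] / tau)
    return out, c_end


def _validate_grid(t_grid: np.ndarray) -> float:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValidationError("t_grid must be a 1-d array with >= 2 points")
    dt = np.diff(t_grid)
    if np.any(dt <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * max(dt[0], 1e-12) + 1e-12:
        raise ValidationError("t_grid must be uniform")
    return float(dt[0])


def simulate_occupancies(
    rates: RateSet,
    protocol: ApplicationProtocol,
    t_grid: np.ndarray,
    p0: np.ndarray | None = None,
    mk0: float = 0.0,
    transient: str = "expm",
) -> StateOccupancy:
    """Solve the master equation over an application protocol.

    The simulation starts with all occupancy in R at glutamate onset (agonist
    binding steps are not modelled; before onset the channel carries no
    current and occupancies are held at R).  Within each epoch the effective
    MK-801 concentration relaxes toward the epoch's nominal value with the
    protocol's exchange_tau; each (filtered) sub-interval is propagated with
    the exact constant-coefficient propagator.

    Parameters
    ----------
    p0, mk0 : optional
        Explicit initial occupancies and effective MK-801 concentration at
        ``t_grid[0]``; when given, the glutamate-onset rule is skipped
        (used by the MK-801 fit, which starts from a stated steady state).
    transient : {"expm", "ode"}
        Integrator for concentration transients: exact per-sample matrix
        exponentials, or the adaptive ODE fast path.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    _validate_grid(t_grid)
    n = len(t_grid)
    p_out = np.zeros((n, 4))

    if p0 is not None:
        p0 = np.asarray(p0, dtype=float)
        if p0.shape != (4,) or abs(p0.sum() - 1.0) > 1e-8 or np.any(p0 < -1e-12):
            raise ValidationError("p0 must be a probability vector of length 4")
        start_t = t_grid[0]
        start_idx = 0
        c_prev = mk0
    else:
        onset = protocol.glutamate_onset()
        if onset is None:
            # no agonist ever applied: channel stays closed
            p_out[:, R] = 1.0
            return StateOccupancy.from_matrix(t_grid, p_out)
        start_idx = int(np.searchsorted(t_grid, onset - 1e-12))
        p_out[:start_idx, R] = 1.0
        if start_idx >= n:
            return StateOccupancy.from_matrix(t_grid, p_out)
        start_t = t_grid[start_idx]
        p0 = np.zeros(4)
        p0[R] = 1.0
        c_prev = 0.0

    # build a gap-free sequence of (t_start, t_end, mk801) intervals covering
    # [start_t, t_grid[-1]]; gaps between epochs are zero-concentration washes
    bounds: list[tuple[float, float, float]] = []
    cursor = start_t
    t_last = t_grid[-1]
    for e in protocol.epochs:
        if e.t_end <= cursor:
            continue
        if e.t_start > cursor:
            bounds.append((cursor, min(e.t_start, t_last), 0.0))
            cursor = e.t_start
        if cursor >= t_last:
            break
        bounds.append((max(e.t_start, cursor), min(e.t_end, t_last), e.mk801))
        cursor = e.t_end
        if cursor >= t_last:
            break
    if cursor < t_last:
        bounds.append((cursor, t_last, 0.0))

    p_cur = p0
    idx = start_idx
    for (t0, t1, c_target) in bounds:
        if t1 <= t0:
            continue
        hi = int(np.searchsorted(t_grid, t1 + 1e-12))
        seg_idx = np.arange(idx, hi)
        if len(seg_idx) == 0:
            # epoch falls between grid points: still evolve the state
            seg, c_prev = _simulate_segment(
                rates, c_prev, c_target, protocol.exchange_tau,
                np.array([0.0, t1 - t0]), p_cur, transient)
            p_cur = seg[-1]
            continue
        t_rel = t_grid[seg_idx] - t0
        # evolve from t0 to the first grid point of the segment
        seg, _ = _simulate_segment(
            rates, c_prev, c_target, protocol.exchange_tau,
            np.concatenate([[0.0], t_rel]) if t_rel[0] > 0 else t_rel,
            p_cur, transient)
        if t_rel[0] > 0:
            seg = seg[1:]
        p_out[seg_idx] = seg
        # state and effective concentration at the end of the interval
        tail, c_prev = _simulate_segment(
            rates, c_prev, c_target, protocol.exchange_tau,
            np.array([0.0, t1 - t0]), p_cur, transient)
        p_cur = tail[-1]
        idx = hi

    occ = StateOccupancy.from_matrix(t_grid, p_out)
    total = occ.p.sum(axis=1)
    if np.max(np.abs(total - 1.0)) > 1e-7:  # pragma: no cover
        raise RuntimeError("occupancy conservation violated beyond tolerance")
    return occ
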