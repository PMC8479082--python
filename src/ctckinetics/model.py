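"""Two-compartment kinetic model of CTC exchange between a paired tumor-bearing
mouse (TBM) and healthy mouse (HM).

The circulatory system of each mouse is treated as a well-mixed container of
blood volume ``V``.  CTCs enter the TBM circulation from the tumor at a
constant generation (intravasation) rate ``r_gen`` and are cleared from both
circulations by first-order kinetics with rate constant
``K_clear = ln(2) / t_half``.  A peristaltic pump continuously exchanges blood
between the two mice at volumetric flow rate ``Q``, so CTCs leave each mouse at
rate ``C(t) * Q`` where ``C = n / V`` is the instantaneous concentration.  Two
in-line counters record the transfer rates ``r1(t) = C1(t) Q`` (TBM -> HM) and
``r2(t) = C2(t) Q`` (HM -> TBM).

Writing ``q = Q`` in mL/min and letting ``a = q / V`` denote the per-cell
sampling hazard, the deterministic model is the linear ODE system::

    dn1/dt = -a n1 + a n2 - K_clear n1 + r_gen      (tumor-bearing mouse)
    dn2/dt =  a n1 - a n2 - K_clear n2              (healthy mouse)

At steady state (dn/dt = 0) the counter rates obey, with the dimensionless
group ``k = K_clear V / q``::

    r1 / r2 = 1 + k
    r2      = r_gen / (k (k + 2))

which inverts to the two closed-form estimators used to analyse experiments::

    r_gen = (r1 - r2) (1 + r1 / r2)              [CTCs/min]
    t_half = (V / q) ln(2) / (r1 / r2 - 1)       [min]

Internally everything is expressed in minutes, mL, and cells; the half-life is
converted to seconds only at the reporting boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

LN2 = math.log(2.0)

__all__ = [
    "ExchangeParams",
    "SystemState",
    "SteadyStateRates",
    "ExchangeTrajectory",
    "ode_rhs",
    "integrate",
    "steady_state_rates",
    "steady_state_counts",
    "estimate_generation_rate",
    "estimate_half_life",
]


@dataclass(frozen=True)
class ExchangeParams:
    """Physiological and pump parameters governing one blood-exchange run.

    Parameters
    ----------
    r_gen:
        CTC generation (intravasation) rate, CTCs/min.  May be zero.
    t_half_s:
        Circulatory half-life, seconds.  Exactly one of ``t_half_s`` and
        ``k_clear`` must be supplied; the other is filled in via
        ``K_clear * t_half = ln 2``.
    k_clear:
        First-order clearance rate constant, 1/min.
    V:
        Total blood volume of each mouse, mL (default 1.75, the midpoint of
        the 1.5-2 mL range typical of an adult mouse).
    Q:
        Pump volumetric flow rate, uL/min (default 60).
    transport_delay:
        Tubing transit time per direction, min (default 2).
    duration:
        Experiment length, min (default 240).
    """

    r_gen: float
    t_half_s: float | None = None
    k_clear: float | None = None
    V: float = 1.75
    Q: float = 60.0
    transport_delay: float = 2.0
    duration: float = 240.0

    def __post_init__(self) -> None:
        if self.r_gen < 0:
            raise ValueError("r_gen must be >= 0")
        if self.t_half_s is None and self.k_clear is None:
            raise ValueError("provide one of t_half_s or k_clear")
        if self.t_half_s is not None and self.k_clear is not None:
            prod = self.k_clear * (self.t_half_s / 60.0)
            if not math.isclose(prod, LN2, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent t_half_s and k_clear: K*t_half = {prod!r}, "
                    f"expected ln(2) = {LN2!r}"
                )
        if self.t_half_s is None:
            object.__setattr__(self, "t_half_s", 60.0 * LN2 / self.k_clear)
        if self.k_clear is None:
            object.__setattr__(self, "k_clear", 60.0 * LN2 / self.t_half_s)
        for name in ("t_half_s", "k_clear", "V", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Q < 0:
            raise ValueError("Q must be >= 0")
        if self.transport_delay < 0:
            raise ValueError("transport_delay must be >= 0")
        if self.q > self.V:
            # exchange should be slow relative to blood-volume turnover
            warnings.warn(
                f"pump flow {self.q} mL/min exceeds blood volume {self.V} mL "
                "per minute; the well-mixed assumption is questionable",
                stacklevel=2,
            )

    @property
    def q(self) -> float:
        """Pump flow rate in mL/min."""
        return self.Q / 1000.0

    @property
    def sampling_hazard(self) -> float:
        """Per-cell hazard of being drawn into the exchange line, 1/min (q/V)."""
        return self.q / self.V

    @property
    def k_dimensionless(self) -> float:
        """Clearance-to-sampling ratio ``k = K_clear V / q``."""
        return self.k_clear / self.sampling_hazard


@dataclass(frozen=True)
class SystemState:
    """CTC counts in both mice at one instant (cells, cells, minutes)."""

    n1: float
    n2: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("CTC counts must be non-negative")

    def concentrations(self, params: ExchangeParams) -> tuple[float, float]:
        """(C1, C2) in cells/mL, with C = n / V."""
        return self.n1 / params.V, self.n2 / params.V


@dataclass(frozen=True)
class SteadyStateRates:
    """Steady-state counter rates (CTCs/min): r1 = TBM->HM, r2 = HM->TBM."""

    r1: float
    r2: float

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("counter rates must be non-negative")

    @property
    def ratio(self) -> float:
        return self.r1 / self.r2


def ode_rhs(state: SystemState, params: ExchangeParams) -> tuple[float, float]:
    """Instantaneous time derivatives (dn1/dt, dn2/dt) in cells/min.

    This is the delay-free form of the model; :func:`integrate` additionally
    supports a transport lag on the inter-mouse transfer terms.
    """
    a = params.sampling_hazard
    k = params.k_clear
    dn1 = -a * state.n1 + a * state.n2 - k * state.n1 + params.r_gen
    dn2 = a * state.n1 - a * state.n2 - k * state.n2
    return dn1, dn2


def steady_state_rates(params: ExchangeParams) -> SteadyStateRates:
    """Closed-form steady-state counter rates.

    With ``k = K_clear V / q``: ``r2 = r_gen / (k (k + 2))`` and
    ``r1 = (1 + k) r2``.  Requires ``r_gen > 0`` and ``K_clear > 0``
    (with no clearance the system grows without bound).
    """
    if params.r_gen <= 0:
        raise ValueError("steady state requires r_gen > 0")
    if params.Q <= 0:
        raise ValueError("steady-state exchange rates require Q > 0")
    if params.k_clear <= 0:
        raise ValueError("no steady state exists for K_clear = 0 (unbounded growth)")
    k = params.k_dimensionless
    r2 = params.r_gen / (k * (k + 2.0))
    r1 = (1.0 + k) * r2
    return SteadyStateRates(r1=r1, r2=r2)


def steady_state_counts(params: ExchangeParams) -> tuple[float, float]:
    """Steady-state CTC counts (n1, n2) in each mouse, cells."""
    rates = steady_state_rates(params)
    a = params.sampling_hazard
    return rates.r1 / a, rates.r2 / a


def estimate_generation_rate(rates: SteadyStateRates) -> float:
    """CTC generation rate from steady-state counter rates, CTCs/min.

    ``r_gen = (r1 - r2)(1 + r1/r2)``.  A result below zero (r1 < r2) is
    non-physical under the model and is flagged with a warning.
    """
    if rates.r2 <= 0:
        raise ValueError("generation-rate estimator undefined for r2 = 0")
    r_gen = (rates.r1 - rates.r2) * (1.0 + rates.r1 / rates.r2)
    if r_gen < 0:
        warnings.warn(
            "r1 < r2 gives a negative generation rate; non-physical under the "
            "exchange model",
            stacklevel=2,
        )
    return r_gen


def estimate_half_life(
    rates: SteadyStateRates, V: float = 1.75, Q: float = 60.0
) -> float:
    """Circulatory half-life from steady-state counter rates, in seconds.

    ``t_half = (V/Q) ln(2) / (r1/r2 - 1)`` with V in mL and Q in uL/min.
    Requires ``r1 > r2 > 0``; otherwise the implied half-life is infinite or
    negative, which is outside the model.
    """
    if rates.r2 <= 0 or rates.r1 <= rates.r2:
        raise ValueError(
            f"half-life estimator requires r1 > r2 > 0, got r1={rates.r1}, "
            f"r2={rates.r2}"
        )
    t_half_min = (V / (Q / 1000.0)) * LN2 / (rates.ratio - 1.0)
    return 60.0 * t_half_min


@dataclass
class ExchangeTrajectory:
    """Deterministic model solution on a time grid.

    All arrays are aligned with ``t`` (minutes).  ``cum_sampled*`` are the
    running integrals of the counter rates (cells drawn into each exchange
    line); ``cum_detected*`` lag them by the transport delay and are the
    expected cumulative counter readings.  ``cum_cleared`` integrates
    ``K_clear (n1 + n2)``.
    """

    t: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    cum_sampled1: np.ndarray
    cum_sampled2: np.ndarray
    cum_detected1: np.ndarray
    cum_detected2: np.ndarray
    cum_cleared: np.ndarray
    params: ExchangeParams = field(repr=False)

    @property
    def in_transit(self) -> np.ndarray:
        """Expected number of cells inside the tubing at each time."""
        return (self.cum_sampled1 - self.cum_detected1) + (
            self.cum_sampled2 - self.cum_detected2
        )

    def return_fraction(self) -> float:
        """Cumulative returned / transferred fraction, ``int r2 / int r1``."""
        return float(self.cum_sampled2[-1] / self.cum_sampled1[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.t,
                "n1": self.n1,
                "n2": self.n2,
                "r1": self.r1,
                "r2": self.r2,
                "cum_detected1": self.cum_detected1,
                "cum_detected2": self.cum_detected2,
            }
        )


def integrate(
    params: ExchangeParams,
    initial: SystemState | None = None,
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-9,
) -> ExchangeTrajectory:
    """Numerically integrate the exchange model on ``t_grid``.

    With a non-zero ``transport_delay`` tau the transfer terms are lagged
    (method of steps): blood sampled from one mouse at time ``t`` reaches the
    other mouse, and its counter, at ``t + tau``.  The tubing is taken to be
    cell-free before the start of the experiment, so delayed inflows are zero
    for ``t < t0 + tau``.

    The augmented state also integrates the sampled-cell and cleared-cell
    totals so that cumulative counter readings and the conservation identity
    ``r_gen (t - t0) + n(t0) = n1 + n2 + in_transit + cleared``
    are available without post-hoc quadrature.
    """
    if initial is None:
        initial = SystemState(0.0, 0.0, 0.0)
    if t_grid is None:
        t_grid = np.arange(initial.t, initial.t + params.duration + 1e-9, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be a 1-D sequence of at least two times")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not math.isclose(t_grid[0], initial.t, abs_tol=1e-12):
        raise ValueError("t_grid must start at initial.t")

    a = params.sampling_hazard
    kc = params.k_clear
    tau = params.transport_delay
    t0, t_end = float(t_grid[0]), float(t_grid[-1])

    # y = [n1, n2, cum_sampled1, cum_sampled2, cum_cleared]
    y0 = np.array([initial.n1, initial.n2, 0.0, 0.0, 0.0])

    segments: list = []  # (t_lo, t_hi, OdeSolution)
    _EPS = 1e-9

    def eval_full(t: float) -> np.ndarray:
        """Evaluate the augmented state at any integrated time (tolerant of
        floating-point segment boundaries)."""
        if t <= t0 + _EPS:
            return y0
        for lo, hi, sol in segments:
            if lo - _EPS <= t <= hi + _EPS:
                return sol(min(max(t, lo), hi))
        raise RuntimeError(f"time {t} outside integrated range")

    def past(t: float) -> tuple[float, float]:
        """(n1, n2) at a lagged time; the tubing is cell-free before t0."""
        if t < t0:
            return 0.0, 0.0
        y = eval_full(t)
        return float(y[0]), float(y[1])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n1, n2 = y[0], y[1]
        if tau > 0:
            p1, p2 = past(t - tau)
        else:
            p1, p2 = n1, n2
        out1, out2 = a * n1, a * n2  # sampling into the exchange lines
        dn1 = -out1 + a * p2 - kc * n1 + params.r_gen
        dn2 = a * p1 - out2 - kc * n2
        return np.array([dn1, dn2, out1, out2, kc * (n1 + n2)])

    if tau > 0:
        boundaries = list(np.arange(t0, t_end, tau)) + [t_end]
    else:
        boundaries = [t0, t_end]

    y = y0
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            method="DOP853",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on [{lo}, {hi}] with params {params}: "
                f"{sol.message}"
            )
        segments.append((lo, hi, sol.sol))
        y = sol.y[:, -1]

    Y = np.array([eval_full(t) for t in t_grid])
    n1, n2 = Y[:, 0], Y[:, 1]
    s1, s2, cleared = Y[:, 2], Y[:, 3], Y[:, 4]

    def eval_lagged(col: int) -> np.ndarray:
        if tau <= 0:
            return Y[:, col].copy()
        out = np.empty(len(t_grid))
        for i, t in enumerate(t_grid):
            out[i] = 0.0 if t - tau < t0 else eval_full(t - tau)[col]
        return out

    return ExchangeTrajectory(
        t=t_grid,
        n1=n1,
        n2=n2,
        r1=a * n1,
        r2=a * n2,
        cum_sampled1=s1,
        cum_sampled2=s2,
        cum_detected1=eval_lagged(2),
        cum_detected2=eval_lagged(3),
        cum_cleared=cleared,
        params=params,
    )
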