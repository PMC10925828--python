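"""Deterministic forward models for cell-population growth.

Two models drive everything downstream:

* single-species logistic growth, ``dN/dt = r N (1 - N/K)``, solved in
  closed form;
* the two-species Lotka-Volterra competition system,

  .. math::

     dN_1/dt = r_1 N_1 (1 - (N_1 + \\alpha N_2)/K_1)

     dN_2/dt = r_2 N_2 (1 - (N_2 + \\beta N_1)/K_2)

  integrated with classic fixed-step 4th-order Runge-Kutta.

``alpha`` is the per-capita competitive effect of line 2 on line 1
(measured in units of line-1 density) and ``beta`` the effect of line 1
on line 2.  Negative coefficients model facilitation; mutualistic
blow-up is detected against a configurable ceiling and flagged rather
than raised, so exhaustive grid searches over (alpha, beta) stay total.

Populations are clamped at zero (extinction is absorbing), matching the
biology of a well: a lineage driven below zero cells cannot recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogisticParams",
    "CompetitionSystem",
    "Trajectory",
    "logistic_solution",
    "simulate_logistic",
    "simulate_competition",
    "DEFAULT_CEILING",
]

#: Population ceiling (cells) above which a trajectory is flagged divergent.
DEFAULT_CEILING = 1e9


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic growth model.

    Parameters
    ----------
    r : float
        Per-capita growth rate (per day); must be positive.
    K : float
        Carrying capacity (cells per well); must be positive.
    """

    r: float
    K: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r) and math.isfinite(self.K)):
            raise ValueError("r and K must be finite")
        if self.r <= 0 or self.K <= 0:
            raise ValueError(f"r and K must be positive, got r={self.r}, K={self.K}")


@dataclass(frozen=True)
class CompetitionSystem:
    """Parameters of the two-species Lotka-Volterra competition system.

    ``alpha`` is the competitive impact of line 2 on line 1, ``beta`` the
    impact of line 1 on line 2 (both dimensionless, in units of the
    affected line's own density).  Either may be negative (facilitation).
    """

    r1: float
    r2: float
    K1: float
    K2: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        vals = (self.r1, self.r2, self.K1, self.K2, self.alpha, self.beta)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("growth rates must be positive")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("carrying capacities must be positive")

    def with_coefficients(self, alpha: float, beta: float) -> "CompetitionSystem":
        """Return a copy with the competition coefficients replaced."""
        return CompetitionSystem(self.r1, self.r2, self.K1, self.K2, alpha, beta)


@dataclass
class Trajectory:
    """Population sizes of one or two species on an ordered time grid.

    ``values`` has shape ``(n_species, n_times)``; ``times`` are days
    since initialization (t=0 at the first observation).
    """

    times: np.ndarray
    values: np.ndarray
    species: tuple[str, ...]
    divergent: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a nonempty 1-d array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.species), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.species)} species x {self.times.size} times"
            )
        if not self.divergent:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("trajectory values must be finite")
            if np.any(self.values < 0):
                raise ValueError("trajectory values must be non-negative")

    def series(self, species: str) -> np.ndarray:
        """Values of one species by label."""
        return self.values[self.species.index(species)]


def _check_finite(name: str, *vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite input {v!r}")


def logistic_solution(params: LogisticParams, n0: float, t) -> float | np.ndarray:
    """Closed-form logistic growth ``N(t)``.

    ``N(t) = K n0 e^{rt} / (K + n0 (e^{rt} - 1))``, the exact solution of
    ``dN/dt = r N (1 - N/K)`` from ``N(0) = n0``.  Zero is absorbing and
    the result always lies between ``n0`` and ``K``.

    Parameters
    ----------
    params : LogisticParams
    n0 : float
        Initial population (cells), >= 0.
    t : float or array
        Time(s) in days, >= 0.

    Returns
    -------
    float or ndarray
        Population at time ``t``; scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_finite("logistic_solution", n0, float(np.min(t_arr)), float(np.max(t_arr)))
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if n0 == 0:
        out = np.zeros_like(t_arr)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
    # K / (1 + ((K - n0)/n0) e^{-rt}): algebraically equal to the textbook
    # K n0 e^{rt} / (K + n0 (e^{rt} - 1)) but exact at n0 = K and immune to
    # e^{rt} overflow at large t.
    e = np.exp(-params.r * t_arr)
    out = params.K / (1.0 + (params.K - n0) / n0 * e)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def simulate_logistic(params: LogisticParams, n0: float, times) -> Trajectory:
    """Sample the closed-form logistic curve at the given times.

    ``times`` must be strictly increasing and start at 0 (days since the
    first observation).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    values = np.atleast_1d(logistic_solution(params, n0, times))
    return Trajectory(times=times, values=values[np.newaxis, :], species=("species_1",))


def _lv_rates(n1, n2, r1, r2, K1, K2, alpha, beta):
    """LV time-derivatives; works on scalars or broadcasting arrays."""
    d1 = r1 * n1 * (1.0 - (n1 + alpha * n2) / K1)
    d2 = r2 * n2 * (1.0 - (n2 + beta * n1) / K2)
    return d1, d2


def integrate_lv_batch(
    r1, r2, K1, K2, alpha, beta,
    n0_1: float, n0_2: float,
    times, step: float,
    ceiling: float = DEFAULT_CEILING,
):
    """RK4-integrate the LV system for a batch of parameter sets at once.

    All six parameters may be arrays of a common shape ``(G,)`` (or
    scalars); the two initial conditions are shared.  Between consecutive
    sample times the interval is divided into ``ceil(dt/step)`` equal RK4
    substeps, so samples land exactly on the requested times and the
    effective step never exceeds ``step``.

    Returns
    -------
    n1, n2 : ndarray, shape (G, n_times)
        Sampled populations (clamped at zero from below).
    divergent : ndarray of bool, shape (G,)
        True where any population exceeded ``ceiling`` during integration.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise ValueError("times must be strictly increasing")
    if step <= 0:
        raise ValueError("step must be positive")
    if times.size > 1 and step > np.min(dts) + 1e-12:
        raise ValueError("step must not exceed the minimum spacing of times")

    r1, r2, K1, K2, alpha, beta = np.broadcast_arrays(
        *[np.atleast_1d(np.asarray(p, dtype=float))
          for p in (r1, r2, K1, K2, alpha, beta)]
    )
    shape = r1.shape
    n1 = np.full(shape, float(n0_1))
    n2 = np.full(shape, float(n0_2))
    divergent = np.zeros(shape, dtype=bool)

    out1 = np.empty(shape + (times.size,))
    out2 = np.empty(shape + (times.size,))
    out1[..., 0] = n1
    out2[..., 0] = n2

    hard_cap = 10.0 * ceiling  # numeric clamp to avoid overflow after flagging
    for i, dt in enumerate(dts):
        nsub = max(1, int(math.ceil(dt / step - 1e-9)))
        h = dt / nsub
        for _ in range(nsub):
            k1a, k1b = _lv_rates(n1, n2, r1, r2, K1, K2, alpha, beta)
            k2a, k2b = _lv_rates(n1 + 0.5 * h * k1a, n2 + 0.5 * h * k1b,
                                 r1, r2, K1, K2, alpha, beta)
            k3a, k3b = _lv_rates(n1 + 0.5 * h * k2a, n2 + 0.5 * h * k2b,
                                 r1, r2, K1, K2, alpha, beta)
            k4a, k4b = _lv_rates(n1 + h * k3a, n2 + h * k3b,
                                 r1, r2, K1, K2, alpha, beta)
            n1 = n1 + (h / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
            n2 = n2 + (h / 6.0) * (k1b + 2 * k2b + 2 * k3b + k4b)
            np.maximum(n1, 0.0, out=n1)
            np.maximum(n2, 0.0, out=n2)
            divergent |= (n1 > ceiling) | (n2 > ceiling)
            np.minimum(n1, hard_cap, out=n1)
            np.minimum(n2, hard_cap, out=n2)
        out1[..., i + 1] = n1
        out2[..., i + 1] = n2
    return out1, out2, divergent


def integrate_lv_scalar(
    sys: CompetitionSystem,
    n0_1: float,
    n0_2: float,
    horizon: float,
    step: float,
    ceiling: float = DEFAULT_CEILING,
    stop_below: float | None = None,
    check_every: int = 100,
):
    """Fast scalar RK4 path for a single LV system (pure Python floats).

    Integrates from t=0 to ``horizon``.  If ``stop_below`` is given,
    integration stops early (checked every ``check_every`` steps) once one
    population is below it while the other is above — the outcome is then
    already decided.

    Returns ``(n1, n2, t_reached, divergent)``.
    """
    r1, r2 = sys.r1, sys.r2
    K1, K2 = sys.K1, sys.K2
    a, b = sys.alpha, sys.beta
    n1, n2 = float(n0_1), float(n0_2)
    nsteps = max(1, int(math.ceil(horizon / step - 1e-9)))
    h = horizon / nsteps
    t = 0.0
    for i in range(nsteps):
        k1a = r1 * n1 * (1.0 - (n1 + a * n2) / K1)
        k1b = r2 * n2 * (1.0 - (n2 + b * n1) / K2)
        x1, x2 = n1 + 0.5 * h * k1a, n2 + 0.5 * h * k1b
        k2a = r1 * x1 * (1.0 - (x1 + a * x2) / K1)
        k2b = r2 * x2 * (1.0 - (x2 + b * x1) / K2)
        x1, x2 = n1 + 0.5 * h * k2a, n2 + 0.5 * h * k2b
        k3a = r1 * x1 * (1.0 - (x1 + a * x2) / K1)
        k3b = r2 * x2 * (1.0 - (x2 + b * x1) / K2)
        x1, x2 = n1 + h * k3a, n2 + h * k3b
        k4a = r1 * x1 * (1.0 - (x1 + a * x2) / K1)
        k4b = r2 * x2 * (1.0 - (x2 + b * x1) / K2)
        n1 += (h / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
        n2 += (h / 6.0) * (k1b + 2 * k2b + 2 * k3b + k4b)
        if n1 < 0.0:
            n1 = 0.0
        if n2 < 0.0:
            n2 = 0.0
        t += h
        if n1 > ceiling or n2 > ceiling:
            return n1, n2, t, True
        if stop_below is not None and (i + 1) % check_every == 0:
            if (n1 < stop_below) != (n2 < stop_below):
                return n1, n2, t, False
    return n1, n2, t, False


def simulate_competition(
    sys: CompetitionSystem,
    n0_1: float,
    n0_2: float,
    times,
    step: float = 0.01,
    ceiling: float = DEFAULT_CEILING,
) -> Trajectory:
    """Integrate the two-species LV system and sample it at ``times``.

    Fixed-step classic RK4 with step ``step`` (days).  A species starting
    at zero stays at zero; populations are clamped at zero from below.
    Any population exceeding ``ceiling`` marks the trajectory divergent
    (``Trajectory.divergent``) instead of raising.
    """
    if n0_1 < 0 or n0_2 < 0:
        raise ValueError("initial populations must be non-negative")
    n1, n2, div = integrate_lv_batch(
        sys.r1, sys.r2, sys.K1, sys.K2, sys.alpha, sys.beta,
        n0_1, n0_2, times, step, ceiling,
    )
    values = np.vstack([np.atleast_1d(n1.squeeze()), np.atleast_1d(n2.squeeze())])
    return Trajectory(
        times=np.asarray(times, dtype=float),
        values=values,
        species=("species_1", "species_2"),
        divergent=bool(np.any(div)),
    )
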