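"""Exhaustive grid-search estimation of growth and competition parameters.

The logistic parameters (r, K) of each replicate growth curve, and the
competition coefficients (alpha, beta) of each co-culture well, are
estimated by simulating the model at every point of a discretized
parameter grid and selecting the point with the lowest root mean square
error (RMSE) against the observed counts.  The default grids are
r in [0.01, 1] step 0.01 per day, K in [1e4, 1e6] step 1e4 cells
(10,000 combinations), and alpha, beta each in [-100, 100] step 1.

The first observed count initializes the model (n0 is not fitted) and
observation days are mapped to t = day - first_day, so fitting starts
once cells have attached and the population is growing.

Tie-breaking among equal-RMSE grid points is deterministic and
parsimony-leaning: smallest r then smallest K for the logistic fit;
smallest |alpha|, then |beta|, then the algebraically smaller value for
the competition fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .growth import CompetitionSystem, LogisticParams, integrate_lv_batch

__all__ = [
    "GridSpec",
    "GrowthCurve",
    "LogisticFitResult",
    "CompetitionFitResult",
    "rmse",
    "count_grid_combinations",
    "fit_logistic_grid",
    "fit_competition_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Inclusive-endpoint parameter grids for the exhaustive searches.

    Each axis enumerates ``floor((max - min)/step) + 1`` values
    ``min, min+step, ...``.  Defaults are the standard assay grids
    (10,000 (r, K) combinations; 201 x 201 (alpha, beta) combinations).
    """

    r_min: float = 0.01
    r_max: float = 1.0
    r_step: float = 0.01
    K_min: float = 1e4
    K_max: float = 1e6
    K_step: float = 1e4
    alpha_min: float = -100.0
    alpha_max: float = 100.0
    alpha_step: float = 1.0
    beta_min: float = -100.0
    beta_max: float = 100.0
    beta_step: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi, st, name in (
            (self.r_min, self.r_max, self.r_step, "r"),
            (self.K_min, self.K_max, self.K_step, "K"),
            (self.alpha_min, self.alpha_max, self.alpha_step, "alpha"),
            (self.beta_min, self.beta_max, self.beta_step, "beta"),
        ):
            if lo > hi:
                raise ValueError(f"{name}: min > max")
            if st <= 0:
                raise ValueError(f"{name}: step must be positive")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    def r_values(self) -> np.ndarray:
        return self._axis(self.r_min, self.r_max, self.r_step)

    def K_values(self) -> np.ndarray:
        return self._axis(self.K_min, self.K_max, self.K_step)

    def alpha_values(self) -> np.ndarray:
        return self._axis(self.alpha_min, self.alpha_max, self.alpha_step)

    def beta_values(self) -> np.ndarray:
        return self._axis(self.beta_min, self.beta_max, self.beta_step)


def count_grid_combinations(grid: GridSpec, which: str = "logistic") -> int:
    """Number of grid points evaluated by a search.

    ``which`` is ``"logistic"`` (the (r, K) axes) or ``"competition"``
    (the (alpha, beta) axes).  The default logistic grid has 10,000
    combinations; the default competition grid 201 x 201 = 40,401.
    """
    if which == "logistic":
        return grid.r_values().size * grid.K_values().size
    if which == "competition":
        return grid.alpha_values().size * grid.beta_values().size
    raise ValueError(f"unknown axis pair {which!r}")


@dataclass
class GrowthCurve:
    """One replicate's observed counts over days for one cell line.

    ``condition`` is one of ``monoculture``, ``coculture``,
    ``transwell_mono``, ``transwell_co``.
    """

    line: str
    condition: str
    ratio_label: str
    replicate: str
    days: np.ndarray
    counts: np.ndarray
    experiment: str = "exp1"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.days.shape != self.counts.shape or self.days.ndim != 1:
            raise ValueError("days and counts must be 1-d arrays of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(~np.isfinite(self.counts)):
            raise ValueError("counts must be finite")

    @property
    def n_obs(self) -> int:
        return self.days.size

    @property
    def rel_times(self) -> np.ndarray:
        """Days since the first observation (t=0 at first count)."""
        return self.days - self.days[0]

    @property
    def n0(self) -> float:
        """First observed count, used to initialize the model."""
        return float(self.counts[0])

    def key(self) -> tuple:
        return (self.experiment, self.condition, self.ratio_label,
                self.replicate, self.line)


@dataclass(frozen=True)
class LogisticFitResult:
    """Best (r, K) grid point for one growth curve."""

    params: LogisticParams
    rmse: float
    n_grid_evaluated: int
    tie_count: int


@dataclass(frozen=True)
class CompetitionFitResult:
    """Best (alpha, beta) grid point for one co-culture well."""

    alpha: float
    beta: float
    rmse: float
    n_grid_evaluated: int
    tie_count: int
    n_divergent: int
    fixed: CompetitionSystem = field(repr=False)

    @property
    def system(self) -> CompetitionSystem:
        """Fixed monoculture rates combined with the fitted coefficients."""
        return self.fixed.with_coefficients(self.alpha, self.beta)


def rmse(simulated, observed) -> float:
    """Root mean square error between two equal-length series.

    For multi-species fits pass the residuals of both species
    concatenated, so each lineage's observations weigh equally.
    """
    sim = np.asarray(simulated, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if sim.shape != obs.shape:
        raise ValueError(f"length mismatch: {sim.size} vs {obs.size}")
    if sim.size == 0:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def fit_logistic_grid(curve: GrowthCurve, grid: GridSpec | None = None) -> LogisticFitResult:
    """Exhaustive (r, K) search minimizing RMSE to one growth curve.

    The closed-form logistic solution is evaluated at every grid point,
    initialized at the curve's first observed count.  Deterministic:
    equal-RMSE ties resolve to the smallest r, then the smallest K.

    Raises if the curve has fewer than 3 observations or starts at zero
    cells (r is unidentifiable from an extinct well).
    """
    grid = grid or GridSpec()
    if curve.n_obs < 3:
        raise ValueError("need at least 3 observations to fit")
    if curve.n0 == 0:
        raise ValueError("first count is zero: growth rate unidentifiable")
    rs = grid.r_values()
    Ks = grid.K_values()
    t = curve.rel_times
    n0 = curve.n0
    # (nr, nK, nt) closed-form evaluation; r outer/K inner so argmin's
    # first-occurrence rule implements the tie-break order.
    e = np.exp(-rs[:, None] * t[None, :])  # (nr, nt)
    K3 = Ks[None, :, None]
    sim = K3 / (1.0 + (K3 - n0) / n0 * e[:, None, :])
    sq = np.mean((sim - curve.counts[None, None, :]) ** 2, axis=2)
    flat = sq.ravel()
    best = int(np.argmin(flat))
    best_rmse = float(np.sqrt(flat[best]))
    ties = int(np.sum(flat == flat[best]))
    i_r, i_k = divmod(best, Ks.size)
    return LogisticFitResult(
        params=LogisticParams(r=float(rs[i_r]), K=float(Ks[i_k])),
        rmse=best_rmse,
        n_grid_evaluated=int(flat.size),
        tie_count=ties,
    )


def fit_competition_grid(
    curve_pair: tuple[GrowthCurve, GrowthCurve],
    fixed: CompetitionSystem,
    grid: GridSpec | None = None,
    step: float = 0.01,
    ceiling: float = 1e9,
) -> CompetitionFitResult:
    """Exhaustive (alpha, beta) search for one co-culture well.

    The monoculture-estimated rates and capacities in ``fixed`` are held
    constant; only the competition coefficients vary.  Every grid pair is
    integrated (RK4, step ``step`` days) from the paired first-day counts,
    and the RMSE pools both lines' residuals at all observation days.
    Divergent simulations (population beyond ``ceiling``) score +inf.

    Ties resolve to the smallest |alpha|, then |beta|, then the
    algebraically smaller coefficient.
    """
    grid = grid or GridSpec()
    c1, c2 = curve_pair
    if not np.array_equal(c1.days, c2.days):
        raise ValueError("paired curves must share identical observation days")
    if c1.n_obs < 3:
        raise ValueError("need at least 3 observations to fit")

    alphas = grid.alpha_values()
    betas = grid.beta_values()
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    a_flat, b_flat = A.ravel(), B.ravel()
    # tie-break order: |alpha|, |beta|, alpha, beta
    order = np.lexsort((b_flat, a_flat, np.abs(b_flat), np.abs(a_flat)))
    a_sorted, b_sorted = a_flat[order], b_flat[order]

    t = c1.rel_times
    n1, n2, divergent = integrate_lv_batch(
        fixed.r1, fixed.r2, fixed.K1, fixed.K2, a_sorted, b_sorted,
        c1.n0, c2.n0, t, step, ceiling,
    )
    resid1 = n1 - c1.counts[None, :]
    resid2 = n2 - c2.counts[None, :]
    sq = 0.5 * (np.mean(resid1 ** 2, axis=1) + np.mean(resid2 ** 2, axis=1))
    sq[divergent] = np.inf
    best = int(np.argmin(sq))
    best_sq = sq[best]
    ties = int(np.sum(sq == best_sq)) if np.isfinite(best_sq) else int(divergent.sum())
    return CompetitionFitResult(
        alpha=float(a_sorted[best]),
        beta=float(b_sorted[best]),
        rmse=float(np.sqrt(best_sq)) if np.isfinite(best_sq) else float("inf"),
        n_grid_evaluated=int(a_sorted.size),
        tie_count=ties,
        n_divergent=int(divergent.sum()),
        fixed=fixed,
    )
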