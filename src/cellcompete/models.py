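"""Model/Results interface over the grid-search fits.

``LogisticGrowthModel`` and ``CompetitionModel`` wrap the exhaustive
grid searches in the familiar fit-and-results idiom: construct the model
from data, call :meth:`fit`, and read estimates, fit diagnostics and a
``summary()`` table off the returned results object.  Phase-plane
analysis (isoclines, outcome classification, outcome simulation) hangs
off the competition results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    CompetitionFitResult,
    GridSpec,
    GrowthCurve,
    LogisticFitResult,
    fit_competition_grid,
    fit_logistic_grid,
)
from .growth import CompetitionSystem, LogisticParams, logistic_solution, simulate_competition
from .outcomes import (
    InteractionClass,
    IsoclineSet,
    OutcomeClass,
    classify_interaction,
    classify_outcome,
    isocline_intercepts,
    outcome_map,
    simulate_outcome,
)

__all__ = ["LogisticGrowthModel", "LogisticGrowthResults",
           "CompetitionModel", "CompetitionResults"]


def _curve_from_frame(df: pd.DataFrame, **filters) -> GrowthCurve:
    from .io import frame_to_curves

    sub = df
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    curves = frame_to_curves(sub)
    if len(curves) != 1:
        raise ValueError(
            f"filters {filters} select {len(curves)} curves; need exactly 1"
        )
    return curves[0]


class LogisticGrowthModel:
    """Logistic growth model for one replicate growth curve.

    Parameters are estimated by exhaustive (r, K) grid search minimizing
    RMSE; the first observed count initializes the trajectory.

    Examples
    --------
    >>> model = LogisticGrowthModel(curve)
    >>> res = model.fit()
    >>> res.r, res.K, res.rmse  # doctest: +SKIP
    """

    def __init__(self, curve: GrowthCurve, grid: GridSpec | None = None):
        self.curve = curve
        self.grid = grid or GridSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: GridSpec | None = None,
                       **filters) -> "LogisticGrowthModel":
        """Build from a long count table, selecting one curve by column
        filters (e.g. ``line="DFT1", replicate="rep1"``)."""
        return cls(_curve_from_frame(df, **filters), grid=grid)

    def fit(self) -> "LogisticGrowthResults":
        return LogisticGrowthResults(self, fit_logistic_grid(self.curve, self.grid))


class LogisticGrowthResults:
    """Fitted logistic growth parameters for one curve."""

    def __init__(self, model: LogisticGrowthModel, fit: LogisticFitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> LogisticParams:
        return self._fit.params

    @property
    def r(self) -> float:
        return self._fit.params.r

    @property
    def K(self) -> float:
        return self._fit.params.K

    @property
    def rmse(self) -> float:
        return self._fit.rmse

    @property
    def tie_count(self) -> int:
        return self._fit.tie_count

    @property
    def n_grid_evaluated(self) -> int:
        return self._fit.n_grid_evaluated

    def predict(self, times=None) -> np.ndarray:
        """Fitted curve at ``times`` (days since first observation)."""
        if times is None:
            times = self.model.curve.rel_times
        return np.atleast_1d(
            logistic_solution(self.params, self.model.curve.n0, times)
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve.counts - self.fittedvalues

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Logistic growth fit (exhaustive grid search)",
            "=" * 48,
            f"curve:          {c.line} / {c.condition} / {c.ratio_label} / {c.replicate}",
            f"observations:   {c.n_obs} (days {c.days[0]:g}-{c.days[-1]:g})",
            f"n0 (day {c.days[0]:g}):    {c.n0:,.0f} cells",
            "-" * 48,
            f"r (per day):    {self.r:.2f}",
            f"K (cells):      {self.K:,.0f}",
            f"RMSE (cells):   {self.rmse:,.1f}",
            f"grid points:    {self.n_grid_evaluated:,} (ties at optimum: {self.tie_count})",
        ]
        return "\n".join(lines)


class CompetitionModel:
    """Two-line Lotka-Volterra competition model for one co-culture well.

    Monoculture-estimated rates and capacities are fixed; the two
    competition coefficients are estimated by exhaustive (alpha, beta)
    grid search on the pooled RMSE of both lines' counts.
    """

    def __init__(self, curve_line1: GrowthCurve, curve_line2: GrowthCurve,
                 fixed: CompetitionSystem, grid: GridSpec | None = None,
                 step: float = 0.01):
        self.curve_line1 = curve_line1
        self.curve_line2 = curve_line2
        self.fixed = fixed
        self.grid = grid or GridSpec()
        self.step = step

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fixed: CompetitionSystem,
                       line1: str, line2: str, grid: GridSpec | None = None,
                       step: float = 0.01, **filters) -> "CompetitionModel":
        c1 = _curve_from_frame(df, line=line1, **filters)
        c2 = _curve_from_frame(df, line=line2, **filters)
        return cls(c1, c2, fixed, grid=grid, step=step)

    def fit(self) -> "CompetitionResults":
        fit = fit_competition_grid((self.curve_line1, self.curve_line2),
                                   self.fixed, self.grid, step=self.step)
        return CompetitionResults(self, fit)


class CompetitionResults:
    """Fitted competition coefficients plus phase-plane diagnostics."""

    def __init__(self, model: CompetitionModel, fit: CompetitionFitResult):
        self.model = model
        self._fit = fit

    @property
    def alpha(self) -> float:
        return self._fit.alpha

    @property
    def beta(self) -> float:
        return self._fit.beta

    @property
    def system(self) -> CompetitionSystem:
        return self._fit.system

    @property
    def rmse(self) -> float:
        return self._fit.rmse

    @property
    def tie_count(self) -> int:
        return self._fit.tie_count

    @property
    def n_grid_evaluated(self) -> int:
        return self._fit.n_grid_evaluated

    @property
    def n_divergent(self) -> int:
        return self._fit.n_divergent

    @property
    def fittedvalues(self) -> np.ndarray:
        """(2, n_times) fitted trajectories at the observation days."""
        traj = simulate_competition(
            self.system, self.model.curve_line1.n0, self.model.curve_line2.n0,
            self.model.curve_line1.rel_times, step=self.model.step,
        )
        return traj.values

    @property
    def resid(self) -> np.ndarray:
        obs = np.vstack([self.model.curve_line1.counts,
                         self.model.curve_line2.counts])
        return obs - self.fittedvalues

    def isoclines(self) -> IsoclineSet:
        return isocline_intercepts(self.system)

    def classify_outcome(self) -> OutcomeClass:
        return classify_outcome(self.system)

    def classify_interaction(self, zero_band: float = 0.5) -> InteractionClass:
        return classify_interaction(self.alpha, self.beta, zero_band)

    def simulate_outcome(self, start_fraction_line1: float, **kwargs):
        return simulate_outcome(self.system, start_fraction_line1, **kwargs)

    def outcome_map(self, fractions, **kwargs):
        return outcome_map(self.system, fractions, **kwargs)

    def summary(self) -> str:
        c1, c2 = self.model.curve_line1, self.model.curve_line2
        f = self.model.fixed
        lines = [
            "Lotka-Volterra competition fit (exhaustive grid search)",
            "=" * 56,
            f"well:            {c1.ratio_label} ({c1.line}:{c2.line}) / "
            f"{c1.replicate} / {c1.experiment}",
            f"fixed rates:     r1={f.r1:.3g}, r2={f.r2:.3g}, "
            f"K1={f.K1:,.0f}, K2={f.K2:,.0f}",
            "-" * 56,
            f"alpha (2 on 1):  {self.alpha:g}",
            f"beta  (1 on 2):  {self.beta:g}",
            f"RMSE (cells):    {self.rmse:,.1f}",
            f"grid points:     {self.n_grid_evaluated:,} "
            f"(ties: {self.tie_count}, divergent: {self.n_divergent})",
            f"interaction:     {self.classify_interaction().value}",
            f"outcome regime:  {self.classify_outcome().value}",
        ]
        return "\n".join(lines)
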