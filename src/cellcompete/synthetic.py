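"""Synthetic co-culture experiment generator.

Emulates the in-vitro assay that produces the count tables the pipeline
analyses: wells plated with 1e5 cells total, sampled daily for 14 days
in triplicate (direct cultures) or every 2 days in duplicate (transwell
cultures), with live-cell counts derived from flow-cytometer events via

    count = (gated events / analysed volume) * well volume (1 mL).

The generating truth is the deterministic growth model (logistic for
monocultures and transwell compartments, Lotka-Volterra for direct
co-cultures), initialized at the plated cell numbers on the first
sampling day.  Observation noise composes two sources:

* multiplicative lognormal well-to-well/handling noise with a given CV
  (mean-one factor, drawn independently per observation);
* counting noise on flow events, Poisson with mean
  ``concentration x analysed volume``.  When the full well volume is
  analysed every cell is seen and the count is exact (no sampling).

Identical seeds yield identical datasets; zero-cell wells stay at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import GrowthCurve
from .growth import CompetitionSystem, LogisticParams, integrate_lv_batch, logistic_solution

__all__ = [
    "CultureDesign",
    "NoiseModel",
    "generate_monoculture",
    "generate_coculture",
    "generate_transwell",
]

#: Default direct-culture sampling days (daily over the 14-day assay).
DIRECT_DAYS = tuple(range(1, 15))
#: Default transwell sampling days (every 2 days).
TRANSWELL_DAYS = tuple(range(1, 15, 2))


@dataclass(frozen=True)
class CultureDesign:
    """Plate layout of one synthetic experiment.

    ``fractions_line1`` are the starting fractions of line 1 per
    co-culture condition (defaults cover an advantage to line 1, a
    balanced start, and an advantage to line 2).  ``total_cells`` is the
    plated total per well.
    """

    kind: str = "coculture"  # monoculture | coculture | transwell
    fractions_line1: tuple[float, ...] = (0.8, 0.5, 0.3)
    total_cells: float = 1e5
    days: tuple[int, ...] = DIRECT_DAYS
    replicates: int = 3
    experiments: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("monoculture", "coculture", "transwell"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if any(f < 0 or f > 1 for f in self.fractions_line1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.total_cells <= 0:
            raise ValueError("total_cells must be positive")
        if len(self.days) < 1:
            raise ValueError("need at least one sampling day")
        if self.replicates < 1 or self.experiments < 1:
            raise ValueError("replicates and experiments must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise settings for the synthetic flow counts."""

    cv: float = 0.10
    analysed_volume_ml: float = 0.1
    well_volume_ml: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not 0 < self.analysed_volume_ml <= self.well_volume_ml:
            raise ValueError("analysed volume must be in (0, well volume]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _observe(true_counts: np.ndarray, noise: NoiseModel,
             rng: np.random.Generator) -> np.ndarray:
    """Apply lognormal handling noise and flow counting noise."""
    true_counts = np.asarray(true_counts, dtype=float)
    if noise.cv > 0:
        sigma = math.sqrt(math.log1p(noise.cv ** 2))
        factor = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                               size=true_counts.shape)
    else:
        factor = 1.0
    abundance = true_counts * factor
    if noise.analysed_volume_ml >= noise.well_volume_ml:
        return abundance  # whole well analysed: every cell counted
    conc = abundance / noise.well_volume_ml
    expected_events = conc * noise.analysed_volume_ml
    events = rng.poisson(expected_events).astype(float)
    return events / noise.analysed_volume_ml * noise.well_volume_ml


def _ratio_label(frac1: float) -> str:
    p1 = round(100 * frac1)
    return f"{p1}:{100 - p1}"


def generate_monoculture(
    design: CultureDesign,
    params: dict[str, LogisticParams],
    noise: NoiseModel,
) -> list[GrowthCurve]:
    """Synthetic monoculture growth curves, one per line and replicate.

    Each well is plated with ``design.total_cells`` of a single line; the
    logistic truth runs from that count at the first sampling day.
    """
    rng = noise.rng()
    days = np.asarray(design.days, dtype=float)
    t = days - days[0]
    curves = []
    for e in range(design.experiments):
        for line in sorted(params):
            truth = np.atleast_1d(logistic_solution(params[line],
                                                    design.total_cells, t))
            for rep in range(design.replicates):
                counts = _observe(truth, noise, rng)
                curves.append(GrowthCurve(
                    line=line, condition="monoculture",
                    ratio_label="100:0", replicate=f"rep{rep + 1}",
                    days=days.copy(), counts=counts,
                    experiment=f"exp{e + 1}",
                ))
    return curves


def generate_coculture(
    design: CultureDesign,
    sys: CompetitionSystem,
    noise: NoiseModel,
    lines: tuple[str, str] = ("DFT1", "DFT2"),
    step: float = 0.01,
) -> list[GrowthCurve]:
    """Synthetic direct co-culture curves, paired per well.

    Each well starts with ``frac * total`` cells of line 1 and the
    remainder of line 2; both lines are observed from the same well at
    the same days (so curves come in pairs sharing experiment, ratio and
    replicate).  Truth is the LV system integrated from the plated split.
    """
    if any(not 0 < f < 1 for f in design.fractions_line1):
        raise ValueError("co-culture fractions must be interior to (0, 1)")
    rng = noise.rng()
    days = np.asarray(design.days, dtype=float)
    t = days - days[0]
    curves = []
    for e in range(design.experiments):
        for frac in design.fractions_line1:
            n0_1 = frac * design.total_cells
            n0_2 = (1.0 - frac) * design.total_cells
            n1, n2, div = integrate_lv_batch(
                sys.r1, sys.r2, sys.K1, sys.K2, sys.alpha, sys.beta,
                n0_1, n0_2, t, step,
            )
            if np.any(div):
                raise ValueError("generating system diverges; lower alpha/beta")
            truth = {lines[0]: np.atleast_1d(n1.squeeze()),
                     lines[1]: np.atleast_1d(n2.squeeze())}
            label = _ratio_label(frac)
            for rep in range(design.replicates):
                for line in lines:
                    counts = _observe(truth[line], noise, rng)
                    curves.append(GrowthCurve(
                        line=line, condition="coculture",
                        ratio_label=label, replicate=f"rep{rep + 1}",
                        days=days.copy(), counts=counts,
                        experiment=f"exp{e + 1}",
                    ))
    return curves


def generate_transwell(
    design: CultureDesign,
    params: dict[str, LogisticParams],
    co_rate_offsets: dict[str, float] | None = None,
    noise: NoiseModel | None = None,
) -> list[GrowthCurve]:
    """Synthetic transwell curves: well-compartment cells only.

    The membrane prevents contact, so each compartment grows
    logistically; a co-culture condition may shift a line's growth rate
    by an additive offset (``co_rate_offsets``, per day), emulating
    diffusible-factor effects.  Only well-compartment cells are counted.
    """
    noise = noise or NoiseModel()
    co_rate_offsets = co_rate_offsets or {}
    rng = noise.rng()
    days = np.asarray(design.days, dtype=float)
    t = days - days[0]
    curves = []
    for e in range(design.experiments):
        for condition in ("transwell_mono", "transwell_co"):
            for line in sorted(params):
                p = params[line]
                if condition == "transwell_co":
                    offset = co_rate_offsets.get(line, 0.0)
                    p = LogisticParams(r=p.r + offset, K=p.K)
                truth = np.atleast_1d(logistic_solution(p, design.total_cells, t))
                for rep in range(design.replicates):
                    counts = _observe(truth, noise, rng)
                    curves.append(GrowthCurve(
                        line=line, condition=condition,
                        ratio_label="100:0", replicate=f"rep{rep + 1}",
                        days=days.copy(), counts=counts,
                        experiment=f"exp{e + 1}",
                    ))
    return curves
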