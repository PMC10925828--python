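"""End-to-end analysis: monoculture fits -> competition fits -> outcomes.

``run_full_analysis`` reproduces the full assay analysis on a long count
table: per-replicate logistic fits with median/CI summaries and
rank-sum comparisons between lines; monoculture means fixed into the
Lotka-Volterra equations; per-well (alpha, beta) fits with their own
summaries and alpha-vs-beta comparison; interaction and phase-plane
outcome classification; an outcome map over starting fractions with a
separatrix estimate; and, when transwell data are present, the
mono-vs-co growth-rate comparison per line.

No multiple-testing correction is applied to the comparison p-values;
each comparison is reported as-is.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import GridSpec, GrowthCurve
from .growth import CompetitionSystem
from .models import CompetitionModel, LogisticGrowthModel
from .outcomes import classify_interaction, classify_outcome, outcome_map
from .stats import aggregate_parameter, median_ci, wilcoxon_rank_sum

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of the analysis pipeline, file-serializable.

    Defaults mirror the standard assay settings: the 10,000-point (r, K)
    grid, the step-1 (alpha, beta) grid, 95% CIs for direct cultures and
    85% for the transwell comparison, RK4 step 0.01 day, a one-cell
    extinction threshold and a 100-day outcome horizon.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    ci_level: float = 0.95
    transwell_ci_level: float = 0.85
    integration_step: float = 0.01
    extinction_threshold: float = 1.0
    horizon: float = 100.0
    total_cells: float = 1e5
    outcome_fractions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    zero_band: float = 0.5
    pool_variants: bool = True
    line1: str = "DFT1"
    line2: str = "DFT2"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        d["outcome_fractions"] = list(self.outcome_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = GridSpec(**d["grid"])
        if "outcome_fractions" in d:
            d["outcome_fractions"] = tuple(d["outcome_fractions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Structured output of the full analysis."""

    config: AnalysisConfig
    monoculture_fits: pd.DataFrame
    monoculture_summary: pd.DataFrame
    comparisons: pd.DataFrame
    fixed_system: CompetitionSystem | None
    competition_fits: pd.DataFrame
    competition_summary: pd.DataFrame
    interaction: str | None
    outcome_class: str | None
    outcome_table: pd.DataFrame
    separatrix: float | None
    transwell_fits: pd.DataFrame
    transwell_summary: pd.DataFrame
    notices: list[str]

    def to_dict(self) -> dict:
        def df(d: pd.DataFrame):
            return d.to_dict(orient="records")

        fx = self.fixed_system
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "monoculture_fits": df(self.monoculture_fits),
            "monoculture_summary": df(self.monoculture_summary),
            "comparisons": df(self.comparisons),
            "fixed_system": None if fx is None else {
                "r1": fx.r1, "r2": fx.r2, "K1": fx.K1, "K2": fx.K2,
                "alpha": fx.alpha, "beta": fx.beta,
            },
            "competition_fits": df(self.competition_fits),
            "competition_summary": df(self.competition_summary),
            "interaction": self.interaction,
            "outcome_class": self.outcome_class,
            "outcome_table": df(self.outcome_table),
            "separatrix": self.separatrix,
            "transwell_fits": df(self.transwell_fits),
            "transwell_summary": df(self.transwell_summary),
            "notices": list(self.notices),
        }

    def save(self, outdir) -> None:
        """Write the JSON report plus one CSV per table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=float)
        )
        for name in ("monoculture_fits", "monoculture_summary", "comparisons",
                     "competition_fits", "competition_summary",
                     "outcome_table", "transwell_fits", "transwell_summary"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)

    def summary(self) -> str:
        out = ["Co-culture competition analysis", "=" * 48]
        if len(self.monoculture_summary):
            out.append("Monoculture logistic fits (median [CI]):")
            for _, row in self.monoculture_summary.iterrows():
                out.append(
                    f"  {row['line']:>8} {row['parameter']}: "
                    f"{row['median']:.3g} [{row['lower']:.3g}, {row['upper']:.3g}] "
                    f"(n={int(row['n'])}, coverage {row['coverage']:.3f})"
                )
        if len(self.comparisons):
            out.append("Comparisons (Wilcoxon rank-sum):")
            for _, row in self.comparisons.iterrows():
                out.append(f"  {row['comparison']}: W={row['statistic']:g}, "
                           f"p={row['pvalue']:.4g}")
        if len(self.competition_summary):
            out.append("Competition coefficients (median [CI]):")
            for _, row in self.competition_summary.iterrows():
                out.append(
                    f"  {row['parameter']}: {row['median']:.3g} "
                    f"[{row['lower']:.3g}, {row['upper']:.3g}] (n={int(row['n'])})"
                )
        if self.interaction:
            out.append(f"Interaction type: {self.interaction}")
        if self.outcome_class:
            out.append(f"Outcome regime:   {self.outcome_class}")
        if self.separatrix is not None:
            out.append(f"Separatrix (line-1 start fraction): {self.separatrix:.3f}")
        for n in self.notices:
            out.append(f"note: {n}")
        return "\n".join(out)


def _base_line(label: str, pool: bool) -> str:
    if pool and label.upper().endswith(("-GFP", "_GFP")):
        return label[:-4]
    return label


def _summarize(fits: pd.DataFrame, group_cols: list[str], value_col: str,
               level: float) -> list[dict]:
    rows = []
    for key, grp in fits.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp[value_col].to_numpy()
        ci = median_ci(vals, level) if vals.size else None
        row = dict(zip(group_cols, key))
        row.update({
            "parameter": value_col,
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
            "lower": ci.lower, "upper": ci.upper,
            "coverage": ci.coverage, "conservative": ci.conservative_flag,
            "n": int(vals.size),
        })
        rows.append(row)
    return rows


def run_full_analysis(curves: list[GrowthCurve],
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the complete pipeline on a set of growth curves.

    Requires monocultures for both lines to fix the competition rates;
    when co-culture or transwell sections are absent they are skipped
    with a notice rather than an error.  The analysis is deterministic
    and invariant to the input ordering of curves.
    """
    config = config or AnalysisConfig()
    notices: list[str] = []
    curves = sorted(curves, key=lambda c: c.key())

    mono = [c for c in curves if c.condition == "monoculture"]
    co = [c for c in curves if c.condition == "coculture"]
    trans = [c for c in curves if c.condition in ("transwell_mono", "transwell_co")]

    # ---- per-replicate logistic fits on monocultures -------------------
    mono_rows = []
    for c in mono:
        res = LogisticGrowthModel(c, config.grid).fit()
        mono_rows.append({
            "experiment": c.experiment, "line": c.line,
            "base_line": _base_line(c.line, config.pool_variants),
            "replicate": c.replicate, "r": res.r, "K": res.K,
            "rmse": res.rmse, "tie_count": res.tie_count,
            "n_grid": res.n_grid_evaluated,
        })
        logger.info("mono fit %s/%s/%s: r=%.3g K=%.4g ties=%d",
                    c.experiment, c.line, c.replicate, res.r, res.K,
                    res.tie_count)
    mono_fits = pd.DataFrame(mono_rows)

    summary_rows: list[dict] = []
    comp_rows: list[dict] = []
    fixed_system = None
    line1, line2 = config.line1, config.line2
    if len(mono_fits):
        for param in ("r", "K"):
            summary_rows += _summarize(mono_fits, ["base_line"], param,
                                       config.ci_level)
        by_line = {ln: grp for ln, grp in mono_fits.groupby("base_line")}
        if line1 in by_line and line2 in by_line:
            for param in ("r", "K"):
                stat, p = wilcoxon_rank_sum(by_line[line1][param],
                                            by_line[line2][param])
                comp_rows.append({
                    "comparison": f"{param}: {line1} vs {line2}",
                    "statistic": stat, "pvalue": p,
                    "n_x": len(by_line[line1]), "n_y": len(by_line[line2]),
                })
            fixed_system = CompetitionSystem(
                r1=aggregate_parameter(by_line[line1]["r"], "mean"),
                r2=aggregate_parameter(by_line[line2]["r"], "mean"),
                K1=aggregate_parameter(by_line[line1]["K"], "mean"),
                K2=aggregate_parameter(by_line[line2]["K"], "mean"),
                alpha=0.0, beta=0.0,
            )
        else:
            notices.append(
                f"monocultures missing for {line1} and/or {line2}; "
                "competition section skipped"
            )
    else:
        notices.append("no monoculture curves; logistic section empty")

    mono_summary = pd.DataFrame(summary_rows).rename(columns={"base_line": "line"})

    # ---- per-well competition fits -------------------------------------
    lv_rows = []
    lv_summary_rows: list[dict] = []
    interaction = outcome_class = None
    separatrix = None
    outcome_rows: list[dict] = []
    report_system = None
    if co and fixed_system is None:
        notices.append("co-culture curves present but rates could not be "
                       "fixed from monocultures; competition fits skipped")
    elif co:
        wells: dict[tuple, dict[str, GrowthCurve]] = {}
        for c in co:
            wells.setdefault(
                (c.experiment, c.ratio_label, c.replicate), {}
            )[_base_line(c.line, config.pool_variants)] = c
        for key in sorted(wells):
            pair = wells[key]
            if line1 not in pair or line2 not in pair:
                notices.append(f"co-culture well {key} lacks both lines; skipped")
                continue
            res = CompetitionModel(pair[line1], pair[line2], fixed_system,
                                   config.grid, step=config.integration_step).fit()
            lv_rows.append({
                "experiment": key[0], "ratio_label": key[1], "replicate": key[2],
                "alpha": res.alpha, "beta": res.beta, "rmse": res.rmse,
                "tie_count": res.tie_count, "n_divergent": res.n_divergent,
                "n_grid": res.n_grid_evaluated,
            })
            logger.info("LV fit %s: alpha=%g beta=%g divergent=%d",
                        key, res.alpha, res.beta, res.n_divergent)
    lv_fits = pd.DataFrame(lv_rows)
    if len(lv_fits):
        for param in ("alpha", "beta"):
            vals = lv_fits[param].to_numpy()
            ci = median_ci(vals, config.ci_level)
            lv_summary_rows.append({
                "parameter": param, "median": ci.median, "mean": float(np.mean(vals)),
                "lower": ci.lower, "upper": ci.upper, "coverage": ci.coverage,
                "conservative": ci.conservative_flag, "n": int(vals.size),
            })
        stat, p = wilcoxon_rank_sum(lv_fits["alpha"], lv_fits["beta"])
        comp_rows.append({
            "comparison": "alpha vs beta", "statistic": stat, "pvalue": p,
            "n_x": len(lv_fits), "n_y": len(lv_fits),
        })
        a_med = float(np.median(lv_fits["alpha"]))
        b_med = float(np.median(lv_fits["beta"]))
        interaction = classify_interaction(a_med, b_med, config.zero_band).value
        report_system = fixed_system.with_coefficients(a_med, b_med)
        outcome_class = classify_outcome(report_system).value
        omap = outcome_map(
            report_system, config.outcome_fractions, config.total_cells,
            config.horizon, config.extinction_threshold,
            config.integration_step,
        )
        for r in omap["results"]:
            outcome_rows.append({
                "start_fraction_line1": r.start_fraction_line1,
                "winner": r.winner, "n1_final": r.n1_final,
                "n2_final": r.n2_final, "t_final": r.t_final,
            })
        separatrix = omap["separatrix"]
    lv_summary = pd.DataFrame(lv_summary_rows)

    # ---- transwell branch ----------------------------------------------
    tw_rows = []
    tw_summary_rows: list[dict] = []
    for c in trans:
        res = LogisticGrowthModel(c, config.grid).fit()
        tw_rows.append({
            "experiment": c.experiment, "line": c.line,
            "base_line": _base_line(c.line, config.pool_variants),
            "condition": c.condition, "replicate": c.replicate,
            "r": res.r, "K": res.K, "rmse": res.rmse,
        })
    tw_fits = pd.DataFrame(tw_rows)
    if len(tw_fits):
        tw_summary_rows += _summarize(tw_fits, ["base_line", "condition"], "r",
                                      config.transwell_ci_level)
        for ln, grp in tw_fits.groupby("base_line"):
            r_mono = grp[grp["condition"] == "transwell_mono"]["r"]
            r_co = grp[grp["condition"] == "transwell_co"]["r"]
            if len(r_mono) and len(r_co):
                stat, p = wilcoxon_rank_sum(r_mono, r_co)
                comp_rows.append({
                    "comparison": f"transwell r mono vs co: {ln}",
                    "statistic": stat, "pvalue": p,
                    "n_x": len(r_mono), "n_y": len(r_co),
                })
    tw_summary = pd.DataFrame(tw_summary_rows).rename(columns={"base_line": "line"})

    logger.info("analysis complete: %d mono fits, %d LV fits, %d transwell "
                "fits, config %s", len(mono_fits), len(lv_fits), len(tw_fits),
                config.config_hash())
    return AnalysisReport(
        config=config,
        monoculture_fits=mono_fits,
        monoculture_summary=mono_summary,
        comparisons=pd.DataFrame(comp_rows),
        fixed_system=report_system or fixed_system,
        competition_fits=lv_fits,
        competition_summary=lv_summary,
        interaction=interaction,
        outcome_class=outcome_class,
        outcome_table=pd.DataFrame(outcome_rows),
        separatrix=separatrix,
        transwell_fits=tw_fits,
        transwell_summary=tw_summary,
        notices=notices,
    )
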