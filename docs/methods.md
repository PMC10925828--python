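# Methods

## Models and estimation

**Logistic growth.** Each growth curve is modelled by
`dN/dt = r N (1 − N/K)`. We evaluate the closed-form solution in the
algebraically equivalent form `N(t) = K / (1 + ((K − n0)/n0) e^{−rt})`,
which is exact at `n0 = K` in floating point (so perfect-fit ties are
exact ties) and immune to `e^{rt}` overflow. Time is measured from the
first observation: day `d` maps to `t = d − d_first`, and `n0` is the
first observed count, not a fitted parameter — fitting starts once cells
have attached and the population is growing, which is also why the
first residual of every fit is zero.

**Lotka–Volterra competition.** Direct co-cultures follow
`dN1/dt = r1 N1 (1 − (N1 + αN2)/K1)`,
`dN2/dt = r2 N2 (1 − (N2 + βN1)/K2)`, with `α` the per-capita effect of
line 2 on line 1 (in units of line-1 density) and `β` the reverse.
Negative coefficients model facilitation. No closed form exists, so the
system is integrated with classic fixed-step 4th-order Runge–Kutta,
default step 0.01 day; between consecutive sample times the interval is
split into equal substeps no longer than the step, so samples land
exactly on observation days. Halving the step changes sampled values by
less than 10⁻⁶ relative (tested), and the integrator is cross-checked
against an adaptive solver. Populations are clamped at zero (extinction
absorbing, preventing sign oscillation under strong competition), and
any trajectory exceeding a ceiling (default 10⁹ cells — mutualistic
blow-up) is flagged divergent rather than raising, keeping grid searches
total; divergent grid points score infinite RMSE. Two code paths share
the scheme: a numpy batch integrator that advances all 40,401 (α, β)
grid points simultaneously, and a pure-Python scalar path with early
exit for single-system outcome simulation; they agree to machine
precision (tested).

**Grid search.** Estimation is exhaustive search minimizing the RMSE
between simulated and observed counts. Default grids: `r` 0.01–1 step
0.01 per day, `K` 10⁴–10⁶ step 10⁴ cells (10,000 combinations); `α, β`
each −100–100 step 1, i.e. 201 × 201 = 40,401 combinations — the count
follows from the stated range and step and is surfaced by
`count_grid_combinations` rather than assumed. For the competition fit
the monoculture-estimated rates and capacities are fixed (as means
across replicate fits) and both lines' residuals at all observation
days are pooled into one RMSE, weighting the lineages equally without
introducing free choices. Fits are per replicate well, yielding a
distribution of estimates across wells and starting ratios. Ties at the
optimum are broken deterministically and parsimony-leaning: smallest
`r` then smallest `K`; smallest `|α|`, then `|β|`, then the
algebraically smaller value. An extinct well (all-zero curve) makes `r`
unidentifiable and is rejected for the logistic fit; an extinct partner
line leaves both coefficients unidentifiable and the tie-break returns
(0, 0).

**Aggregation and comparison.** Replicate estimates are reported as
medians; monoculture parameters are fixed into the competition
equations as means. Median uncertainty uses the exact distribution-free
binomial order-statistic interval: the innermost symmetric pair of
order statistics whose coverage `1 − 2P(Bin(n, ½) ≤ k−1)` reaches the
requested level. At small `n` no pair can reach 95%; the outermost pair
is then returned with its *achieved* coverage and flagged — coverage is
never overstated. Between-group comparisons use the Wilcoxon rank-sum
test: exact permutation enumeration on midranks when the pooled sample
has ≤ 12 observations (ties handled naturally; identical samples give
p = 1), otherwise the continuity- and tie-corrected normal
approximation. GFP-labelled and unlabelled variants of a line pool into
one base line by default (config-switchable), since labelling is an
experimental control, not a biological contrast.

## Phase-plane outcome analysis

Setting each line's growth to zero gives isoclines `N1 = K1 − αN2`
(intercepts `[0, K1/α]`, `[K1, 0]`) and `N2 = K2 − βN1` (intercepts
`[0, K2]`, `[K2/β, 0]`); a coefficient ≤ 0 yields a +∞ intercept by the
limit convention (the isocline never crosses the positive quadrant, so
that exclusion pathway is absent). Comparing `K1` with `K2/β` and `K2`
with `K1/α` gives four regimes: line 1 excludes line 2 when its
isocline lies wholly outside (`K1 > K2/β`, `K2 < K1/α`), the mirror
case for line 2, bistability (initial-condition dependence) when both
inequalities point inward, and coexistence when both point outward.
The classifier follows the phase-plane dynamics and is verified against
long-horizon integration from multiple interior starting points;
equalities are measure-zero boundaries and are reported as such rather
than forced into a regime. Interaction type is the sign pattern of
(α, β) with a configurable near-zero band (default 0.5, half a grid
step): both positive — competition; both negative — mutualism; one
negative, one zero — commensalism; opposite signs — parasitism.

Outcome simulation integrates the system from a chosen starting split
of 10⁵ cells; a line wins when the other drops below an extinction
threshold of 1 cell per well (the dynamics reach zero only
asymptotically, and below one whole cell a lineage is extinct in a
well) while it remains above, within a default 100-day horizon. The
outcome map sweeps starting fractions and bisects the winner flip to
estimate the separatrix of the bistable regime. Horizon, step and
threshold are config-exposed; the classifier-agreement tests use a
longer horizon (1,500 days) and coarser step (0.05 day) because weakly
dominant systems (5% margins) need of order `ln K / (r·margin)` days to
drive the loser below one cell.

With the headline estimates (r1 = 0.40, r2 = 0.76, K1 = 8.15×10⁵,
K2 = 4.2×10⁵, α = 78, β = 15) the system is bistable; simulation puts
the separatrix near a 65–70% line-1 starting fraction (so a 90:10
line-1 start flips the outcome to line-1 exclusion of line 2, while
balanced starts end in line-2 victory). Note that the deterministic
model at these point estimates predicts a line-1 win already from an
80:20 start, whereas the in-vitro assay saw line 2 overtake there —
a reminder that the point-estimate system does not reproduce every
observed well, only the aggregate kinetics.

## Synthetic experiment generator

The generator emulates the assay design: 10⁵ cells plated per well,
daily sampling of triplicate wells for 14 days (direct cultures),
duplicate wells every 2 days for transwell cultures (only
well-compartment cells counted; a co-culture condition may shift a
line's rate by an additive offset, emulating diffusible-factor
effects), optional duplicate experiments. The truth is the
deterministic model initialized at the plated numbers on the first
sampling day — attachment losses between plating and day 1 are not
modelled, consistent with initializing fits at the day-1 count.
Defaults place one co-culture starting fraction in each band the design
used (80%, 50% and 30% line 1).

Observation noise composes the assay's two dominant variance sources:
a mean-one multiplicative lognormal factor per observation (each day's
count comes from a different harvested well; default CV 10%, a
config-exposed placeholder in lieu of the real replicate variance) and
Poisson counting noise on flow events with mean
`concentration × analysed volume` (default 0.1 mL of the 1 mL well),
converted back by the flow formula
`count = events/volume analysed × 1 mL`. When the full well is analysed
the count is exact, giving a noise-free mode for round-trip tests.
Everything is driven by one seed; identical seeds give identical
datasets. The generator does **not** emulate media replacement (the
logistic/LV forms already absorb resource renewal into `r` and `K`),
GFP-transduction effects, FACS gating, or cell morphology — so passing
tests demonstrate estimator correctness under the stated noise
structure, not robustness to every artefact of real cultures.

Two identifiability properties of the design, visible in synthetic runs
and relevant to real data: `K` of a slow line is weakly determined by a
14-day window (the curve is ~96% of `K` at day 14 for r = 0.40, so
plateau noise propagates into `K`), and `α` is weakly determined once
the suppressed line has crashed (the trajectory becomes insensitive to
how hard it is being pushed), giving wide, right-skewed per-well `α`
spreads — mirroring the wide published interval for `α`. The transwell
co-culture rate offset used in the acceptance study (+0.05/day on the
faster line) is our choice of a "slight increase"; at duplicate-well
sample sizes its rank-sum detection is underpowered at 10% noise.

## Problem sizes and other choices

Unit tests run coarse grids (e.g. 34×34 α/β) for speed; the acceptance
tests and `scripts/acceptance.py` use the full 10,000- and 40,401-point
grids. The acceptance study is two experiments of triplicate wells per
condition (18 competition fits) plus a four-well-per-condition
transwell arm — the scale of the original design. Classifier-agreement
sampling draws rates from 0.3–1.0/day, capacities from 10⁵–10⁶ cells
and coefficients log-uniformly from 0.1–50, rejecting systems within 5%
of a regime boundary. The analysis path contains no randomness;
reports are byte-stable given inputs and config, and config files
round-trip losslessly through YAML.

Known limitations: no likelihood-based or gradient estimation (the grid
is the prescribed estimator, and quantization is one step per axis); no
stochastic birth–death dynamics or spatial/mechanical-stress models; no
multiple-testing correction (comparisons are reported as-is, matching
the original analysis); formal stability analysis of the interior
equilibrium is replaced by the isocline inequalities plus simulation.
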