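# Methods

This note records the model equations the package implements, the
numerical choices behind them, and what the synthetic-data experiments
do and do not demonstrate.

## Static mass balance

Each functional group *i* satisfies a production balance

    (P/B)_i · B_i · EE_i = Y_i + Σ_j DC_ij · (Q/B)_j · B_j + E_i + BA_i · B_i

where B is biomass density (t/km²), P/B production per biomass (yr⁻¹,
equal to total mortality Z at demographic equilibrium and to Z + ln λ
for a population growing at finite annual rate λ), Q/B consumption per
biomass, DC_ij the fraction of predator j's diet taken from prey i,
Y catch, E net emigration, BA biomass accumulation, and EE the
ecotrophic efficiency — the fraction of production consumed, caught, or
accumulated within the model (1 − EE is "other" mortality M0/PB).
Energy balance per consumer is Q = P + R + UN·Q with UN the
unassimilated fraction, so respiration R = (1 − UN)·Q − P must be
strictly positive for a feeding consumer; a non-positive R is reported
as a thermodynamic error, never clamped.

Every group supplies three of {B, P/B, Q/B, EE} and the solver fills the
fourth.  Because each term contains at most one unknown per group, the
whole web is one linear system, assembled over all groups and solved
simultaneously; there are no per-group sweeps and hence no order
dependence.  A missing Q/B (or P/B) cannot be inferred from the
production balance — the group's own consumption does not appear in its
own equation — so it must be backed by a growth efficiency GE = P/B ÷
Q/B, which the solver applies directly.  Groups with all four values
supplied have EE recomputed as the output, and a warning is raised if
the supplied value disagrees.  Detritus pools receive egestion (UN·Q)
and non-predation deaths; their EE (consumption of detritus over
inflow) is reported but never constrained to [0, 1].

Defaults where a model is silent: UN = 0.2 for fish and invertebrates
and 0.15 for marine mammals and birds (conventional assimilation
figures), E = 0, BA = 0.

## Foraging-arena dynamics

Biomass dynamics follow

    dB_i/dt = g_i Σ_j Q_ji − Σ_j Q_ij − (M0_i + F_i(t)) · B_i

with g = P/B ÷ Q/B.  Consumption on each trophic link uses the
foraging-arena form

    Q_ij = a_ij v_ij B_i B_j / (2 v_ij + a_ij B_j),

in which prey exchange at rate v between invulnerable refuges and
arenas where the predator searches at rate a.  Setting
v_ij = x_ij · M2_ij(base), with x the link's vulnerability multiplier,
and solving a_ij so the base-year flow is reproduced exactly gives two
structural guarantees: the balanced base is an equilibrium of the
unforced dynamics, and the realized predation mortality M2_ij = Q_ij/B_i
can never exceed x_ij times its base value, whatever the predator does.
x close to 1 therefore means the predator is already near the carrying
capacity its prey supply can support; large x approaches mass action.
x = 1 itself leaves no finite search rate and is rejected at
parameterization.  Groups with positive biomass accumulation (growing
marine-mammal populations entered with P/B = Z + ln λ) have a
correspondingly smaller M0 and grow from the base year toward the
foraging-arena carrying capacity — that emergent saturation is the
mechanism that ends their growth.

Producers use a self-limiting production rate r·B/(1 + h·B), calibrated
so base production matches P/B·B and the production-to-biomass ratio at
vanishing biomass is twice its base value (max relative P/B = 2, the
conventional choice).  The annual primary-production anomaly multiplies
r, with linear interpolation between annual nodes.  Fishing enters as
forced instantaneous rates F(t), annual values held constant within the
year.  Detritus biomass is held constant (a donor pool): the study
questions concern predator–prey and producer forcing, and a constant
pool keeps the unforced base an exact equilibrium without inventing an
unobserved detritus export closure.  Immigration and emigration default
to zero (closed system).

### Integration

The monthly clock is split into sub-steps (default 2).  Plankton-like
groups whose base loss rate exceeds the monthly clock (λ ≥ 12 yr⁻¹)
relax one to two orders of magnitude faster than anything else in the
web; integrating them explicitly at practical step sizes is unstable,
so they are treated quasi-statically — driven to their moving
equilibrium B = gains/loss-rate by damped fixed-point iteration
(relative tolerance 1e−9, classification on the monthly clock so the
treatment does not change with sub-stepping).  The remaining groups take
exponential predictor–corrector steps: writing dB = G − λB and
advancing the linear-loss part exactly, with G and λ averaged between
the predictor and corrector states.  The scheme is second order,
positivity-preserving, and exact at any equilibrium.  An explicit
two-step Adams–Bashforth integrator is available (``integrator="ab2"``)
for webs without fast groups.  Halving the default step changes annual
biomasses by well under 0.1%.  Biomass is floored at 1e−10 of its base
value with a warning count; non-finite states abort with the offending
group and month.

## Multi-stanza age structure

Split species are tracked as numbers-at-age on a monthly grid.  Body
weight follows a von Bertalanffy cube w(a) = (1 − e^{−K a})³ in units of
the asymptotic weight, and per-capita consumption scales as w^{2/3}
(metabolic surface scaling).  Equilibrium survivorship
l(a) = Π exp(−Z_s/12) distributes biomass (Σ l·w) and consumption
(Σ l·w^{2/3}) across stanzas so only the leading stanza's B and Q/B need
observing.  Iteroparous species pool ages beyond 400 months into a plus
group carrying the geometric sum of older survivors, which makes the
equilibrium age structure an exact fixed point of the monthly update;
semelparous (terminal) species die after the final stanza's age span.

The monthly update applies survival exp(−Z_s/12) with Z_s read off the
dynamic model (predation + fishing + other), shifts ages, grows weights
by the baseline von Bertalanffy increments scaled by the stanza's
relative feeding rate, and recruits age 0 in proportion (optionally a
power) to mature-mass-weighted abundance Σ N·max(0, w − w_mat).  With
proportional recruitment the population scale is neutral — trajectories
are driven entirely by the mortality and feeding environment — while the
age structure is attracted to the survivorship equilibrium.  A maturity
weight unreachable within the modelled ages would silently extinguish
the population; it is rejected at initialization instead.

## Fitting

The objective is a weighted sum over reference series of squared
deviations between log observations and log predictions.  For relative
(index) series the catchability q is profiled out in closed form,
q = exp(mean(log obs − log pred)); absolute series use q = 1.

Both searches are deterministic coordinate descents that accept only
SS-decreasing moves, so SS is monotone within and across stages.

*Vulnerabilities* are searched per block (default one block per predator
column; per-link is available but rarely identifiable) on
log(x − 1 + ε) with a golden-section line search per block.  Two
safeguards matter in practice.  First, the window is restricted to
x ∈ [1.01, 99]: below it the link is donor-capped, above it the link is
numerically indistinguishable from mass action, and both extremes are
degenerate fits that data cannot distinguish from their boundary.
Second, a block move must improve SS by at least 1% of its current
value; blocks the data barely inform otherwise drift to arbitrary
values chasing observation noise.  Blocks are visited in descending
order of a one-evaluation sensitivity probe (each block briefly set to
x = 4); descending on an insensitive block first can trap the cyclic
descent in a conditional local minimum.  Ties keep the earlier block in
model order.

*The production anomaly* is one log-scale node per simulated year.  Each
node update moves along the mean-preserving direction e_k − 1/n, so the
log anomaly stays exactly mean-zero — a uniform anomaly is
indistinguishable from the catchability scalings and is excluded by
construction.  Nodes are bounded at |log| ≤ 1.5 and an optional ridge
penalty λ_pp·Σ node² is available (off by default).

*Stage order.*  The pipeline mirrors the natural sequence — fit
vulnerabilities, then search the anomaly — but a vulnerability pass run
before any anomaly is known tends to absorb anomaly-driven variation
into extreme multipliers on mid-trophic links.  The pipeline therefore
alternates (default two cycles), warm-starting each stage: the second
vulnerability pass, run with the first anomaly estimate in place, lets
those blocks relax back toward values the predation data actually
support.  Every stage still only accepts SS-decreasing moves, so the
stage sequence remains monotone.

*Climate comparison.*  The fitted anomaly is taken to log scale,
standardized, and compared to a standardized climate index by yearly
sign agreement and Pearson correlation.

## Synthetic data

The generator builds producer → zooplankton → forage-fish →
salmon-like split species → marine-mammal-like predator webs.  Predator
biomasses are drawn first and scaled so no salmon stanza's predation
plus fishing exceeds 95% of its total mortality; the forage,
zooplankton and producer pools are then sized so the demand on each
equals a drawn EE target times its production.  A web assembled this
way balances with all EE ≤ 0.95 by construction.

Reference data emulate the structure of an agency-derived calibration
set for this kind of study:

- relative-biomass indices with lognormal observation noise
  (σ = 0.1 log units — SS is defined on logs, so the noise is additive
  where the objective lives);
- total-mortality (Z) series for salmon smolt and adult stanzas (the
  kind of series coded-wire-tag cohort reconstruction yields);
- fishing-mortality forcings with declines of 37–84% phased in over
  years 11–21 of the horizon (the mid-1990s restriction pattern);
- census-forced predator growth of 2–6× plateauing two decades in;
- a ±0.2 log-unit producer-productivity square wave with a 6-year
  period (oscillation lengths of one to six years), mean-zero in logs;
- true vulnerability multipliers of 2 (the conventional default) on
  most links and lognormal (median 3) on the predator columns.

The `salish_like` preset instantiates this at 4 split species
(16 stanza groups) and 6 predators over a 42-year horizon starting in
1979.  One seed drives all draws; identical seeds give bit-identical
outputs.

What passing the recovery experiments shows: the simulator, objective
and searches are mutually consistent — data generated by the model at
known vulnerabilities and anomaly lead the pipeline back to that truth
(median |log x error| below 0.5 on fitted blocks, anomaly sign
agreement above 80% of years, monotone SS).  What it does not show:
anything about features of real data the generator omits — seasonal and
spatial predator–prey overlap, hatchery release pulses, cohort-resolved
tag data, time-varying diets, autocorrelated or biased observation
error, and model misspecification generally.

## Problem sizes

The test suite exercises the solver oracle on random webs of up to 10
groups, dynamic properties on 3-group chains and a 10-group stanza web,
and recovery on the `salish_like` preset (26 groups, 2 fitting cycles
with budgets of 400/800 simulator evaluations per stage); the
acceptance script repeats the preset recovery end to end.  These sizes
keep a full run in minutes on one core while leaving every mechanism —
multi-stanza dynamics, forced predators, fishing declines, anomaly
forcing — active.

## Known limitations

- The packaged 1979 northeast Pacific model carries a placeholder diet
  matrix (the source table prints none) and assumed stanza age spans and
  growth constants; it is suitable for structural and arithmetic use,
  not for dynamic inference, and is flagged accordingly.
- Quasi-static treatment of fast groups discards sub-monthly plankton
  transients (relaxation times under ~1 month).
- The coordinate searches are local; they are deterministic and
  monotone but can in principle stop at conditional minima the
  sensitivity ordering does not escape.
- Mortality decomposition attributes predation by predator but does not
  separate additive from compensatory components of M0.
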