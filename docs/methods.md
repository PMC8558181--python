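# Methods

## Model

`tavicea` implements a Markov cohort (state-transition) model for the
cost-effectiveness of transcatheter aortic valve implantation (TAVI) in
severe aortic stenosis, against surgical aortic valve replacement (sAVR)
for intermediate- and high-surgical-risk patients and against medical
therapy for inoperable patients.

The cohort moves monthly through nine health states: NYHA functional
classes I–IV with and without a history of major stroke (eight living
states) plus death, the single absorbing state. Each cycle composes three
competing steps in a fixed order:

1. **death** — the cycle's arm-level mortality probability applies to every
   living state (mortality inputs are arm-level, not state-level, so it must
   act first and uniformly);
2. **major stroke** — among survivors, the cycle's stroke probability moves
   cohort mass from each no-stroke state to the same-class stroke-history
   state (the class is kept, the flag flips and is never cleared);
3. **NYHA movement** — among survivors, the arm's monthly 4×4 row-stochastic
   matrix redistributes classes, applied identically inside the no-stroke
   and stroke blocks.

All other clinical events (bleeding, pacemaker implantation, atrial
fibrillation, hospitalizations, balloon valvuloplasty, re-interventions,
endocarditis, …) are not states: the expected number of events per cohort
member in cycle *t* is (survivor fraction after that cycle's deaths) ×
(per-cycle event probability), and each event is billed at its unit cost in
the cycle of occurrence.

## Input transforms

Clinical inputs arrive as probabilities over month bands (1; 2–6; 7–12;
13–24; … up to 60 for mortality). The band probability *p* over *n* months
becomes a constant monthly probability `1 − (1 − p)^(1/n)`, which compounds
back to *p* exactly. Bands are closed, 1-based months; the per-cycle value
applies uniformly within its band.

- **Mortality beyond the observed 60 months** is extended linearly: an
  ordinary-least-squares line is fitted to the annualized probabilities of
  years 2–5 and evaluated at each later year, converted to monthly and
  clamped to [0, 1] (with a warning when clamping occurs). The fit window is
  configurable, and an alternative `cumulative` mode fits the line to the
  cumulative death fraction instead and differences it back to annual
  conditional probabilities; `interval` is the default because it better
  matches the reference survival results for two of the three risk groups
  (see "Known limitations").
- **Event rates beyond the last observed band** (24 months) carry the last
  band's converted monthly rate forward unchanged to the horizon.

## Economics

Outcomes and costs accrued in cycle *t* are discounted by
`(1 + r)^(−t/12)` with *r* = 3%/year by default. Life years are the
discounted sum of living occupancy × 1/12; QALYs weight each living state
by its annual utility (death ≡ 0). No half-cycle correction is applied by
default (a switch exists); end-of-cycle occupancy is used.

Costs per arm are: the index procedure cost billed once at time zero
(undiscounted) — tariff values in the base case (€30,634 TAVI, €24,675
sAVR, €0 medical therapy, which has no priced "procedure"), micro-costing
values in the scenario (€26,985 / €14,802) — plus discounted expected event
costs. Re-interventions (re-TAVI, re-sAVR) are billed at the respective
tariff procedure cost in every mode; the micro-costing scenario re-prices
the index procedure only. The scenario additionally bills rehabilitation
once at cycle 1 to the uptake fraction (64% sAVR, 6.2% TAVI); its unit cost
is a required configuration input with a clearly-labelled €5,000
placeholder in the packaged micro fixtures (the source tariff value is not
published). "Acute pulmonary oedema" has a unit cost but no incidence
input; it is loaded but unbilled.

Incremental results use unrounded deltas. The ICER divides incremental
cost by incremental (discounted) life years, the ICUR by incremental
QALYs; ratios are undefined (`None`, flagged, never an exception) when the
effect delta is not positive, and dominance is flagged when cost and
effect deltas have opposite beneficial signs.

## Sensitivity analyses

**One-way (tornado).** Every registered scalar input is set to ±20% of its
base value in turn, the full model rerun, and parameters ranked by the
absolute ICUR spread (top 20 reported). Interval probabilities are
registered as one multiplier per (arm, event) pair so a tornado bar is a
clinically meaningful driver; clamped probabilities are flagged.

**Probabilistic (PSA).** 1000 draws by default. Beta distributions
(method of moments) for event/mortality probabilities and utilities,
Normal for tariff-based costs, all sampled independently across parameters;
each draw reruns both arms and records (ΔCost, ΔQALY, ΔLY). Dispersion is
not reported in the source material — the single largest inferential gap in
this implementation — so the default standard error is 20% of the mean
(the OWSA perturbation magnitude), configurable per run. In the default
`multiplier` mode the intervals of one (arm, event) pair share a quantile
(they move together, matching driver-level uncertainty); `per_interval`
mode draws them independently. The stroke/no-stroke utilities of one class
also share a quantile so the decrement ordering survives sampling.
Negative cost draws are resampled (capped, then clamped to 0 with a
warning). Runs are bit-reproducible from the seed.

The acceptability curve reports, over a €0–100,000/QALY grid in €1,000
steps, the fraction of draws with positive net monetary benefit
λ·ΔQALY − ΔCost; the CE-plane export labels each draw's quadrant.

## Synthetic stand-ins

The published supplementary tables holding NYHA transition matrices and
health-state utilities are unavailable, so the package generates labelled
substitutes (`tavicea.synthetic_data`): intervention arms improve one NYHA
class per month with propensity 0.30 (TAVI) / 0.25 (sAVR) during the first
12 cycles, decaying to a quarter of that afterwards, with 1%/month
background progression; the medical arm only progresses (6%/month).
Utilities are 0.85/0.75/0.65/0.55 per NYHA class I–IV with a 0.10 stroke
decrement, identical across arms. These are conventional magnitudes for
this disease area chosen once for structural plausibility — monotone
gradient, post-procedure improvement, no spontaneous improvement under
medical therapy — and are **not** the published values. Consequently every
QALY-dependent output (ICURs, tornado, CEAC) is a demonstration of the
machinery, not a reproduction; cost and life-year outputs do not depend on
these tables at all. Users can supply real tables via the `utilities.csv`
and `nyha_transitions.csv` schemas, after which the pipeline reproduces
whatever ICUR those inputs imply (verified by a CSV round-trip test).

The generator also produces degenerate ground-truth regimes — constant
hazards, frozen NYHA class, flat utilities — whose discounted LY, QALY and
cost reduce to geometric series; the pipeline matches these closed forms to
1e−9, which is the module's main verification role. The synthetic dynamics
do not emulate real-data features such as state-dependent mortality,
utility ageing, or correlated parameter uncertainty, so passing tests
establish internal consistency, not clinical validity.

## Numerical choices and degenerate inputs

- Row-stochasticity is enforced to 1e−10, occupancy mass to 1e−9.
- A band probability of 1 converts to a monthly probability of 1.
- Horizon 0 is allowed and yields zero outcomes and index cost only.
- An all-zero event table stays zero everywhere, carry-forward included;
  a parameter with zero base value is insensitive to multiplicative
  perturbation and ranks last in the tornado.
- Beta sampling collapses to a point mass (with a warning) when the mean is
  0 or 1 or the requested variance is infeasible.
- The cohort starts alive, without stroke history, uniformly over NYHA
  II–IV by default (the initial distribution is not published and is a
  configuration input).
- Whether stroke survivors change class in the stroke cycle is unspecified
  upstream; the model keeps the class and flips the flag.

## Problem sizes

The default horizon is 180 monthly cycles; a base-case comparison runs in a
few milliseconds, the default PSA (1000 draws × 2 arms) in ~15 s.
Sensitivity unit tests use a 60-cycle horizon, and the path-enumeration
oracle runs on 3-state chains over 9 cycles, the largest size for which
exhaustive path enumeration stays trivially cheap.

## Known limitations

- With the documented conventions the model reproduces the reference
  discounted life years closely for the high-risk and inoperable groups and
  overshoots them by ~6% for the intermediate group (where the `cumulative`
  extrapolation mode fits better); no single documented mode matches all
  three groups at once.
- Per-life-year discounted event costs match the reference intermediate-risk
  results almost exactly but diverge for the high-risk and inoperable
  groups (TAVI arms high, medical-therapy arm low), which propagates into
  the cost-per-LYG ratios for those groups. The discrepancy is robust to
  every documented convention switch (at-risk basis, extrapolation mode,
  index discounting, carry-forward) and most plausibly reflects
  unpublished arm-specific cost structure in the original implementation,
  e.g. a running management cost for the medical-therapy arm.
- Parameters are sampled independently in the PSA; no correlation structure
  is available to estimate.
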