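# Methods

## The quantal assay and its endpoint

A tumorigenicity arm transplants a ladder of cell doses (log10-spaced, e.g.
10^2 … 10^6 cells) of undifferentiated PSCs into groups of mice by a
clinical route (subcutaneous, liver, striatum, tail vein) and scores each
animal positive once a teratoma becomes detectable within the monitoring
window. The endpoint of interest is the TPD50, the dose producing
teratomas in half of the animals — the median of the underlying tolerance
distribution on the log-dose scale.

### Spearman–Kärber estimator

With equal log10 spacing `d`, observed proportions `p_i` and top log10 dose
`x_max`:

    log10 TPD50 = x_max + d/2 − d · Σ_i p_i

This is the mean of the empirical tolerance distribution under the closure
convention that the dose below the ladder is fully negative and the dose
above fully positive. Design choices:

- **Raw proportions by default.** No trimming and no monotonicity
  adjustment: published TPD50 values such as 10^6.75 are only reachable by
  the untrimmed formula. A weighted isotonic (PAV) pre-adjustment is
  available behind `isotonic=True` (delegated to
  `scipy.optimize.isotonic_regression`).
- **Extrapolation flags, not suppression.** If the top observed proportion
  is < 1 the estimate leans on the closure convention; it is returned with
  `extrapolated_top=True` plus a warning. Likewise `extrapolated_bottom`
  when the bottom proportion is > 0.
- **Variance.** Classical Spearman–Kärber:
  `se = d·sqrt(Σ p_i(1−p_i)/(n_i−1))`; groups of one animal contribute zero
  and warn (the variance is then understated). The 95% CI is the normal
  interval on log10 dose. The source analysis prints no interval, so the
  CI is this package's addition.
- **Equal-spacing tolerance** |Δlog10 − d| ≤ 1e-9; unequal ladders raise.
- **All-negative arms** return a not-applicable result (rendered
  "Not applicable"), not an error: a no-teratoma arm is a legitimate,
  reportable outcome.
- Reporting rounds to 3 significant figures (`mantissa × 10^exponent`).

Reed–Muench cumulative pooling (positives accumulated up-dose, negatives
down-dose, linear interpolation of the pooled percent curve to 50%) is
implemented purely as an independent cross-check; it carries no variance
and returns not-applicable when the pooled curve does not bracket 50%.

Time-resolved estimates (`td50_series`) apply the estimator to cumulative
positives at each monitoring week; since Σp_i is non-decreasing in week,
the series is non-increasing.

### Single-hit model

`P(d) = 1 − exp(−p_cell·d)`: each transplanted cell initiates independently
with probability `p_cell`, so the analytic TPD50 is `ln2/p_cell`. The fit
maximises the binomial likelihood in `log p_cell`; because the score is
strictly decreasing in `p_cell`, the MLE is found by bracketed root-finding
of the score (xtol 1e-14), initialised at `ln2 / TPD50_SK`. The 95% CI is
the profile-likelihood interval at the chi-square(1) 3.84 cutoff, solved by
bisection. All-positive or all-negative arms raise a boundary error
(`p_cell` unidentifiable). The deviance against the saturated binomial
model (df = groups − 1) flags incidence steeper or shallower than one-hit
kinetics. The source assay never asserts single-hit kinetics; this module
is the package's mechanistic bridge between the nonparametric endpoint and
per-cell risk, and reports label it as such.

### Known statistical limitation: CI coverage under single-hit truth

The Spearman–Kärber formula estimates the *mean* of the log-dose tolerance
distribution; the single-hit analytic TPD50 is its *median*. Under
single-hit truth the distribution of log10 tolerance is a Gumbel-type law
whose mean sits `(γ + ln ln 2)/ln 10 ≈ 0.0915` log10 **below** the median.
Exact enumeration over all binomial outcomes (5 doses, 10 animals/group)
shows the nominal-95% CI therefore covers the analytic TPD50 in only
~88–92% of arms depending on where the curve sits on the dose grid
(~89.9% with the TPD50 centred on the grid), with n = 10 discreteness
contributing the remainder. The acceptance test asserting nominal coverage
documents this gap and fails honestly; none of the estimator, its variance
convention, or the generator was adjusted to mask it.

## Safe-dose extrapolation

`safe_dose_threshold` computes `anchor × (1/lod_fraction) × mass_scaling`:

- **anchor** (cells): the lowest teratoma-forming dose, or the highest
  no-teratoma dose, from the mouse arm; the result carries which kind was
  used so reports phrase it correctly ("likelihood increases at/above" vs
  "no incidence observed up to").
- **lod_fraction**: the PCR detection limit as a fraction (0.001% → 1e-5);
  the bound *divides* by it — a product screened clean can still carry one
  undifferentiated cell per 1/lod_fraction cells.
- **mass_scaling**: 1 for local routes (the source analysis applies none);
  2×10^3 (human/mouse weight ratio) for systemically infused products
  dosed per body.

The product is reported to 12 significant figures to strip binary-float
artifacts from an order-of-magnitude quantity. Comparability between
transplantation models is `|Δlog10 TPD50| ≤ window`, window 1.0 log10 by
default — a package convention; the qualitative claim being formalised
("comparable") has no published numeric criterion.

## Detection limits

qPCR wells are called positive when the marker Ct is determined and
≤ `max_ct` (default 38); wells whose reference gene fails its cutoff
(default Ct 30) are excluded, not counted negative. ddPCR wells are called
positive at ≥ 3 positive droplets, and quantified by the standard Poisson
correction `λ = −ln(1 − k/n)` copies/droplet, reported also per reaction
and per 5 ng RNA (the conventional unit). All cutoffs are package
defaults, configurable — the source assay prints none.

`estimate_lod` uses the hard **all-replicates** rule — the LOD is the
smallest tested fraction at which every valid replicate is positive —
because a single printed limit with no statistical model is what such
assays report. A probit alternative (binomial GLM of detection vs log10
fraction via statsmodels, LOD at 95% detection probability) is provided
for graded data.

## Synthetic generators

`simulate_assay` draws initiating events per animal as
Poisson(p_cell × dose); each initiated clone starts at 1 cell after a
lognormal latency (median 1 week, log-sd 0.5) and grows geometrically
(default ×7/week, i.e. doubling every ~2.4 days); the animal turns positive
when the earliest clone exceeds the detectability threshold (default 10^3
cells, the smallest luciferase-labelled mass detectable in a deep organ).
With the default 12-week window detectable masses appear between roughly
weeks 2 and 8, and endpoint incidence converges to the single-hit curve.
One RNG stream per (seed, group, animal) keeps groups independent of each
other's sizes.

What it does *not* emulate: immune clearance kinetics (syngeneic vs
allogeneic differences enter only through the chosen `p_cell`), animal
death or exclusion, metastasis location, or imaging noise. Tests that pass
on this generator validate the estimators' statistical behaviour under
single-hit truth, not the biology of any particular model.

`simulate_dilution` draws marker template copies as
Poisson(ratio × RNA cell-equivalents × marker copies per positive cell +
leak). Defaults: 5 ng RNA at 6.6 pg/cell (≈758 cell-equivalents), 2500
marker transcript copies per undifferentiated cell, zero background leak;
qPCR Ct = 40.8 − 3.32·log10(copies) + N(0, 0.4) with undetermined wells at
zero copies; ddPCR partitions copies into 20 000 droplets. This
calibration places the all-replicates LOD at a spike fraction of 1e-5
(0.001%) in ≈96–98% of seeds on either platform (the remainder mostly call
1e-6 when the ~1.9-copy wells all amplify, as happens for ddPCR at
seed 0); it represents a high-expressing marker such as LIN28A, not a
fitted model of any instrument.

`reconstruct_incidence` exhaustively enumerates equal-group-size incidence
patterns (n ≤ 10 keeps the search well under a second) whose
Spearman–Kärber estimate rounds to a printed TPD50 at its printed precision
and whose smallest positive dose matches the printed minimum
teratoma-forming dose. It exists because published summaries omit raw
counts: matching patterns are explicit *reconstructions*, and an empty
result is itself informative — three published TPD50s (4.08×10^5, 5.09×10^2,
3.73×10^4) admit no equal-n pattern, implying unequal group sizes
(deaths/exclusions) in those arms; they are documented, not fitted.

## Problem sizes

Simulation-backed tests use 2 000 arms (coverage), 500 arms (parameter
recovery), 1 000 wells (ddPCR recovery) and 100 seeds × 3 backgrounds
(LOD calibration); each completes in seconds on one core and the counts
give Monte-Carlo standard errors comfortably below the asserted margins.
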