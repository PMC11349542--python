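# Methods

This note documents the modelling choices behind the package: the cohort
model and its conventions, the survival machinery, the costing rules, the
uncertainty analyses, what the synthetic-data generator does and does not
emulate, and known limitations.

## Cohort model

**Structure.** A partitioned-survival model with states PFS → PD → death.
Occupancies are read directly from the two fitted survival functions
(PFS = min(S_PFS, S_OS), death = 1 − S_OS, PD = the remainder, clipped at
zero) rather than derived per-cycle transition probabilities. The two
formulations describe the same marginal curves; partitioned survival
reproduces the fitted extrapolations exactly, which is the quantity the
cost-effectiveness ratio depends on. A transition-probability variant
(1 − S(t+Δ)/S(t)) is deliberately out of scope.

**Time grid.** The cycle equals the dosing interval, 21 days. Calendar
conversion uses 1 month = 365.25/12 = 30.4375 days, so one cycle is
21/30.4375 ≈ 0.68993 months; the 10-year (120-month) horizon gives
ceil(120/0.68993) = 174 cycles. Halving the cycle length moves discounted
life-years by < 0.5% (midpoint-rule convergence, tested).

**Half-cycle correction.** Implemented as evaluation of occupancies and
discount factors at cycle midpoints t_k = (k+0.5)·Δ, equivalent to the
trapezoid correction up to O(Δ²).

**Discounting.** (1+r)^(−t_mid/12) with the country's annual rate (China
5%/year, US 3%/year), applied identically to costs and outcomes.

**Outcomes.** LY sums alive occupancy times the cycle length in years;
QALY weights PFS/PD occupancy by utilities 0.79/0.69 (renal-cell-carcinoma
proxies, per the source inputs). Grade ≥3 adverse events contribute a
one-off expected disutility Σ p_AE·|d_AE| lasting one cycle, applied and
discounted at cycle 0. One cycle is the minimal duration consistent with
"all AEs occur in the first cycle" and is a configuration knob in effect
(duration scales linearly with the decrement term).

## Survival fitting and reconstruction

**Parameterizations** (time in months): lognormal (meanlog, sdlog) with
median exp(meanlog); log-logistic S(t) = [1+(t/scale)^shape]^(−1) with
median = scale; Weibull S = exp(−(t/scale)^shape); exponential rate;
gamma (shape, rate); Gompertz hazard h(t) = rate·e^(shape·t), shape free
in sign — negative shape plateaus at exp(rate/shape) and is the documented
exception to S(∞) = 0. The log-logistic scale ≈ median OS in months ties
the convention to the reported trial medians.

**Maximum likelihood.** One shared engine for all six families: the
censored log-likelihood Σ_events log f + Σ_censored log S is maximized by
L-BFGS-B on log-transformed positive parameters (the Gompertz shape
untransformed), polished from five fixed moment-based starts; the best
optimum is kept, making fits deterministic given the data. AIC is the
selection criterion; BIC is reported alongside. AIC ties within 0.01 break
toward fewer parameters, then alphabetical family name. lifelines'
univariate fitters serve as an independent cross-check in the test suite,
not as the implementation.

**Curve reconstruction.** Published curves are consumed as digitized
(time, survival) coordinates. Pseudo individual-patient data are obtained
by the standard at-risk-constrained inversion: within each interval
between published at-risk timepoints, a censoring count is solved
iteratively (censor times spread uniformly over the interval) so that the
implied number at risk matches the next published count; events follow
from the KM step ratios with integer rounding. Deficits up to
max(2, 1% of n) between walk and published count are treated as
digitization/rounding slack; larger deficits raise an error naming the
interval. Without an at-risk table, no censoring is assumed before the end
of follow-up. Survivors are administratively censored at the last curve
time. Digitization jitter that pushes the curve non-monotone by ≤ 0.005 is
repaired by a running-minimum projection; larger violations are errors,
never silently fixed. Round-trip accuracy (KM of the reconstruction vs KM
of the generating sample) is ≤ 0.02 sup-norm on n = 300 fixtures, tested
with and without at-risk tables.

The published information criteria imply the scale of the authors'
reconstruction: BIC − AIC = k(ln n − 2) with k = 2 gives n ≈ 533 for the
pembrolizumab PFS fit — a documentation-level cross-check only, since the
authors' digitized coordinates are not deposited and their exact AIC/BIC
values are therefore not reproducible. The packaged configurations carry
the published fitted parameters directly; the fitting path is validated by
parameter-recovery and family-recovery simulation instead.

## Costing

Per cycle k (discounted at the midpoint factor):

* **Trial drugs** — per-cycle cost × PFS occupancy, per scheduled drug,
  with optional per-drug cycle caps (`max_cycles`; cost accrues while
  k < cap). Cisplatin is capped at 8 cycles per protocol; gemcitabine is
  uncapped.
* **Pembrolizumab cap.** The packaged configurations charge pembrolizumab
  for the entire progression-free period (`max_cycles = null`). This is a
  calibration choice: the published arm totals in both countries are
  reproduced to ≤ 2.6% (incremental costs to < 1%) only when pembrolizumab
  cost is not truncated at the trial's 35-cycle administration limit;
  truncation leaves both pembrolizumab arms ≈ 2 discounted drug-cycles
  short. The cap machinery is fully implemented and tested; analysts who
  want the protocol limit set `max_cycles: 35` in the configuration.
* **Imaging** — a flat per-cycle charge while progression-free, as
  tabulated (the 6-weekly schedule is already folded into the per-cycle
  value). The US configuration uses the same imaging price as China
  (source limitation).
* **Adverse events** — one-time expected cost Σ p_AE·c_AE at cycle 0.
* **Subsequent treatment** — a mix-weighted per-cycle regimen cost charged
  for all PD occupancy, with regimen costs summed from member drugs
  (mFOLFOX = oxaliplatin + folinic acid + fluorouracil; "other" =
  irinotecan + capecitabine). Mix weights are normalized by their sum (an
  identity at base values, which sum to 1.00). No stopping rule is applied
  to the PD stream.

Per-cycle cost values are totals per cycle (pack sizes in the source table
are provenance metadata; body-surface-area dosing is already folded in).
Currency is USD throughout; administration, routine-visit and end-of-life
costs are absent from the source inputs and hence from the model.

## Incremental analysis

ICERs divide unrounded incremental costs by unrounded incremental QALYs
(or LYs); rounding happens only at the reporting layer. Non-positive QALY
increments yield dominance flags instead of ratios. Net monetary benefit
NMB(w) = w·ΔQALY − ΔCost is the probabilistic decision statistic.

**Price threshold.** Incremental cost is affine in any unit price (drug
cost enters linearly through both the on-treatment stream and, for
pembrolizumab, the immunotherapy share of both arms' follow-up mixes), so
the price at which ICER = WTP is found by bisection on [0, base price] to
±$0.01 and cross-checked against the closed-form solve implied by that
linearity. For the China configuration the solver gives ≈ $374/cycle, a
≈ 93% reduction — consistent in magnitude with the source's "~91%"
discussion figures, which are themselves mutually inconsistent at the few
percent level.

**Payer share.** An insurer/patient split scales the patient-facing
incremental cost (and hence ICER) by the patient share, leaving outcomes
unchanged.

## Sensitivity analyses

**One-way.** Each parameter moves to the low and high end of its published
range (±25% of base where none is stated — this includes the discount
rate) with all others at base; bars are ranked by ICER excursion width. A
model failure or dominance case at an extreme is flagged in the output and
the run continues. The configuration objects are immutable, so the base
case cannot be perturbed by a sweep.

**Probabilistic.** 1,000 second-order Monte-Carlo draws. Costs are gamma,
utilities and probabilities beta, each moment-matched with mean = base and
sd = (high − low)/3.92, i.e. the published range is treated as a central
95% interval (the source states the families but not the spread rule; a
25%-of-mean alternative is available via `sd_rule="cv25"`). Disutilities
are drawn as beta on the magnitude scale and re-signed. Draws use one
seeded generator with columns drawn in sorted parameter-name order, so
results are independent of configuration key order and reproducible under
a fixed seed. Survival-curve parameters and the discount rate carry no
published distribution and are held fixed. Utility draws may cross
(u_PD > u_PFS is possible because the published ranges overlap); such
draws are retained, as in the usual second-order convention. Only
non-finite model output causes a draw to be rejected and replaced (count
reported).

## Synthetic data

The generator emulates the data environment of the published analysis:
event times drawn by inverse-CDF from any of the six families (defaults
mirror the four fitted trial curves), with no censoring, administrative
censoring at a fixed horizon, or uniform censoring; and "digitized curve"
fixtures — either the exact model survival function on an even grid with
optional bounded jitter, or the exact KM step function of a simulated
sample with its true at-risk table. It does **not** emulate staggered
accrual, dropout dynamics, digitization bias beyond i.i.d. jitter, or
inter-curve correlation, so passing round-trip tests demonstrate
correctness of the inversion and fitting machinery, not robustness to
every pathology of real plot digitization.

## Verification summary

The base-case outcomes reproduce the published values within ±0.05
LY/QALY in both countries, incremental costs within 1%, and ICERs within
~3%; the remaining ICER gap traces to the incremental-QALY denominator
(ours ≈ 0.142 vs the published unrounded ≈ 0.1385), i.e. to small
differences in the original TreeAge accrual conventions that the published
tables do not pin down further. The China probability of
cost-effectiveness at $38,201.19/QALY is 0% for every tested seed, and the
acceptability curve is monotone in willingness-to-pay.

## Known limitations

* The model inherits all input limitations of the source analysis: proxy
  utilities from other cancers, AE selection (grade ≥3, incidence ≥ 9%),
  no administration or end-of-life costs, US imaging priced at the China
  rate.
* Only two-strategy comparisons are supported (no frontier analysis).
* PSA draws parameters independently (no correlation structure is
  published).
* The patient-assistance ("donation scheme") scenario is not modelled; the
  scheme's dosing/price details are not public.
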