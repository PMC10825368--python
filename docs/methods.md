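# Methods

## Problem setting

`uaeopt` models and optimizes an ultrasound-assisted extraction (UAE)
process in which four factors — ultrasonication power (100–300 W),
temperature (30–70 °C), deep-eutectic-solvent (DES) molar ratio
(0.5–2.5) and DES water content (15–35 %) — drive four measured
responses: total phenolic content (mg GAE/g d.w.), DPPH antioxidant
activity (% inhibition), total anthocyanin content (mg/g d.w.) and
total flavonoid content (mg QE/g d.w.). The computational chain is:
central composite design (CCD) → assay quantification → one ANFIS
surrogate per response → relative-influence analysis → genetic-algorithm
(GA) multi-response optimization.

## Experimental design

The 4-factor CCD comprises the 2⁴ factorial block (coded ±1), two axial
runs per factor at ±α and six center replicates: 16 + 8 + 6 = 30 runs.
The axial distance defaults to α = 2, the rotatable value for four
factors; it is the only choice under which each factor's stated
minimum/maximum are the axial extremes and each factor takes five
distinct levels. The coding map is affine,
`actual = mean + coded·(max − mean)/α`, so coded 0 is the center and ±α
the extremes. Run order is deterministic (factorial in standard order,
axial pairs, then center replicates); randomization of run order is a
wet-lab concern with no computational counterpart here.

## Assay quantification

All four responses come from spectrophotometry:

* **Phenolics / flavonoids** — gallic-acid (quercetin) calibration line
  fitted by ordinary least squares; content = c·V/w where c is the
  concentration read off the inverted line (mg/mL), V the extract
  volume (mL) and w the dry mass (g).
* **DPPH** — % inhibition = (A_blank − A_sample)/A_blank × 100.
* **Anthocyanins** — pH-differential method: corrected absorbance
  A = (A510 − A700)|pH1 − (A510 − A700)|pH4.5, converted to mg/L with
  the cyanidin-3-glucoside constants (MW 449.2 g/mol, ε 26 900
  L·cm⁻¹·mol⁻¹, 1 cm path), then to mg/g d.w. through the extract
  volume per dry mass. The solvent-to-solid ratio defaults to
  25 mL/g. A negative corrected absorbance — possible near zero
  pigment — is clamped to 0 with a warning rather than raised, since it
  is ordinary measurement noise.

## ANFIS surrogate

Each response gets an independent first-order Takagi–Sugeno network on
a grid partition: 3 Gaussian membership functions per input → 3⁴ = 81
rules, each with a linear consequent in the four inputs plus a
constant (405 coefficients). Inputs are internally rescaled to the
coded box [−2, 2] so widths are comparable across factors. Training
splits the records ⌈0.7n⌉/rest into training/checking sets (seeded
shuffle) and runs either

* **hybrid** — per epoch, consequents solved exactly by linear least
  squares with premises frozen, then one normalized gradient step on
  all centers and widths; or
* **backprop** — normalized gradient steps on all parameters,

with the classic step-size schedule (×1.1 after four consecutive error
decreases, ×0.9 after two up/down oscillations; initial step 0.01 in
coded units). The returned model is the epoch snapshot with the lowest
checking RMSE; with `method=None` both trainers run and the
better-checking one wins. Widths are floored at 1e−3 coded units during
gradient updates. Default 500 epochs; in practice the best-checking
snapshot is reached within the first tens of epochs because the LSE
pass does most of the work.

### Numerical choices for the underdetermined consequent solve

A 30-run design (21 training records) — or even the augmented 111-point
set used in the recovery studies — cannot determine 405 consequents.
Two defaults handle this regime:

* **Membership width.** Initial widths are 1.5× the center spacing
  (`width_scale=1.5`, i.e. σ = 3 coded units for m = 3 over [−2, 2]).
  Narrow, weakly overlapping sets make the normalized rule blend change
  steeply between data points, and the exact-interpolation solution
  oscillates wildly there (held-out R² can go strongly negative on a
  smooth quadratic surface); strongly overlapping sets keep the blend —
  and hence the fitted surface — smooth.
* **Spectral truncation.** When the regression system is
  underdetermined, singular values below 1e−2 of the largest are
  truncated (`lse_rcond="auto"`). Those directions are combinations of
  consequents nearly invisible at the data but huge between points;
  dropping them is what prevents the solve from interpolating
  measurement noise. For determined systems plain least squares is
  used, and `rcond=None` forces the textbook minimum-norm solution
  (zero training residual) when exact interpolation is wanted.

With these defaults, surrogates trained on the noise-free CCD + 3⁴
grid reach held-out R² ≥ 0.99 on fresh points of the true surface, and
≥ 0.90 when 2 %-of-range Gaussian noise is added, across seeds.

## Relative influence

The influence of factor j on response k is operationalized as the OLS
slope of the surrogate prediction along a 101-point sweep of coded
x_j ∈ [−α, α] (other factors at center), divided by the sample standard
deviation of the observed response. This single-factor-sweep definition
is deterministic and testable: on synthetic truth the slope over a
symmetric sweep equals the generating linear coefficient exactly
(quadratic terms are orthogonal to the linear trend, interactions
vanish at the center), so recovered signs must match the generator's
sign matrix. Only signs and rankings are interpreted; the magnitudes
depend on the normalization convention.

## Genetic algorithm

The fitness is a weighted sum of min–max-normalized predictions,
Σ_k w_k (ŷ_k − L_k)/(U_k − L_k), maximized over the factor box; L/U
default to the observed response ranges and weights to 1, putting the
fitness on a 0–4 scale. The GA is elitist real-coded: tournament
selection (size 3), BLX-0.5 blend crossover (p = 0.9), per-gene
Gaussian mutation (p = 0.1, SD = 10 % of range) clipped to the box,
2 elites, population 50, 200 generations, plus an archive of the 18
best pairwise-distinct individuals (distance > 1e−6 in range-normalized
units). Elitism makes the best-so-far fitness non-decreasing; clipping
guarantees feasibility of every evaluated individual. On a concave
quadratic with a known interior maximizer the GA lands within far less
than 1 % of each factor's range of the argmax across seeds.

## Synthetic data generator

No raw 30-run dataset is published for this process, so the generator
produces the study conditions synthetically: full quadratic surfaces in
coded units — the canonical family a CCD is built to estimate — with

* linear coefficients |β₁| ~ U(0.5, 1.0), signed by the configured
  sign matrix (defaults follow the published influence signs, e.g.
  phenolics rise with power/molar ratio/water and fall with
  temperature);
* mildly concave pure quadratics β₂ ~ U(−0.25, −0.05), giving each
  response an interior optimum as extraction responses typically have;
* small interactions β_jl ~ U(−0.08, 0.08);
* an affine rescale so each surface's extrema over the coded box equal
  the published response ranges (4.154–8.163 mg GAE/g, 45.588–88.639 %,
  0.452–0.750 mg/g, 0.213–0.545 mg QE/g);
* additive Gaussian noise with SD 2 % of each range (consistent with
  the sub-5 % validation deviations typical of these assays), clipped
  to ±10 % beyond the range so noise cannot produce unphysical values.

What the generator does **not** emulate: raw absorbance-level noise
(assays are tested separately), non-quadratic surface features
(saturation plateaus, thresholds), heteroscedastic or correlated
measurement error, and run-order drift. Passing recovery tests
therefore demonstrates that the pipeline recovers what it assumes —
smooth quadratic-like response fields — not that any real extraction
obeys one.

## Problem sizes used in the test and acceptance runs

Recovery studies train on the 30-run CCD plus a 3⁴ coded grid (111
points), hold out 300 uniform points of the coded box, and use 200
training epochs (the best-checking snapshot is reached long before;
500 remains the library default). The exhaustive reference for the
end-to-end optimization check is a 21⁴ grid search on the true
surface; the GA-found optimum's true fitness is required to be within
2 % of that maximum. Noisy-recovery studies repeat over 5 seeds.

## Known limitations

* The 81-rule architecture is far richer than 30 runs can support; the
  truncated solve and checking-based snapshot selection control but do
  not remove the variance of such surrogates on small noisy designs.
* Influence scores are local (center-sweep) by construction and will
  understate factors whose effect appears only through interactions.
* The GA handles box constraints only; it is a scalarized single-
  objective search, not a Pareto method.
* The scalarization of the four objectives is an equal-weight sum by
  default; different weights move the optimum, and no sensitivity
  analysis over weights is built in.
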