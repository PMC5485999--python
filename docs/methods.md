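# Methods

## Model

The package models the %DNA-in-tail signal of the alkaline comet assay
after one radiotherapy fraction as the total content of five damage
compartments plus a baseline.  Primary breaks `n0` (the alkaline assay
sees both single- and double-strand breaks) are induced during the
beam-on pulse at rate `kcleav * R(t)`, with `R(t)` a rectangular
dose-rate pulse.  No saturation of target sites is modelled: tail
fractions stay far below 100 %DNA, so the pool of intact DNA is treated
as unlimited.  An extended induction mode `kcleav * R * (epsilon + D)`
(cumulative dose `D`, pre-existing-break dose-equivalent `epsilon`) is
implemented for the two-hit picture of fragment liberation, but the
simple mode is the default: with data at a single dose rate the two are
not distinguishable and only rescale `kcleav`.

Detection into a fast or slow repair pathway is first order (`k0,p`).
The chain of intermediate repair steps of each pathway is compressed
into a *delayed* first-order processing step: the transfer from detected
(`n1,p`) to processed (`n2,p`) breaks at time `t` proceeds at
`k1,p * n1,p(t - tr,p)`.  The same delayed term is the outflow of
`n1,p` and the inflow of `n2,p`, so the transfer conserves mass exactly;
this placement is a design choice made here (the delay could also be
applied asymmetrically, which would break conservation).  Final
rejoining of two free fragment ends is second order, `-k2,p * n2,p^2`.
The two pathway blocks are exchangeable (fast/slow is labelling only),
and zeroing the slow-pathway rates yields the nested one-pathway model.

Units: `k0`, `k1` are min^-1; the second-order `k2` is per-%DNA per min;
`kcleav` is %DNA per Gy; delays are min.  Published parameter tables for
this model label every constant min^-1; the numbers are used verbatim as
magnitudes in the working units above, which is the dimensionally
consistent reading of `kcleav*R` (%DNA/min) and `k2*n2^2` (%DNA/min).

The observable is `n0 + n1,fast + n1,slow + n2,fast + n2,slow + bn`:
every damage species is electrophoretically mobile, and `bn` is the
pre-existing background signal, co-estimated during fitting rather than
subtracted.  Pre-treatment samples are ordinary observations at a time
before the pulse, where the model predicts `bn`.

Model time starts at the pulse; observation times are quoted relative to
pulse end, matching how post-treatment sampling times are reported.  The
default pulse is 6 Gy over 2 min (the order of magnitude of a clinical
linac delivery; beam-on time is configurable).

## Numerics

The delay system is integrated by a fixed-step method of steps:
classical RK4 (forward Euler available as a cross-check) on a uniform
grid with the pulse edges inserted as grid points, the delayed `n1`
values read from the stored partial trajectory by linear interpolation,
and zero history before the start.  With steps (default 0.05 min) far
below the delays (~1-20 min), the interpolation error is below the RK4
truncation error; the convergence tests confirm fourth order on a
zero-delay cascade against its matrix-exponential solution.  Beam-on is
decided once per step (each step lies entirely inside or outside the
pulse), which keeps the right-hand side smooth within every step and
makes the delivered dose exact to machine precision.

Zero-history delay equations can transiently overdraw a compartment: the
delayed outflow `k1*n1(t-tr)` does not see the current `n1`.  The
default `limit-outflow` policy restores non-negativity after each step
by moving the overdraft of `n1,p` to its target `n2,p` (the two terms
are the same flux, so total damage is unchanged); `n0` overdrafts are
returned to the detection targets in proportion to `k0,p`, and `n2`
is floored at zero.  Clamp activations are counted on the trajectory.
For fitted-parameter magnitudes (`k1*tr` ≲ 0.4) clamping is a rare
late-time correction; when `k1*tr` approaches 1 the projection becomes
persistent and the computed trajectory is policy-defined to first order
in the step — solver cross-checks are therefore only claimed in the
mildly-clamped regime.

## Parameter estimation

The error of fit is the unweighted sum of squared differences between
the predicted observable and the observed median %DNA in tail (RMSE is
reported alongside).  Rate constants (`kcleav`, `k0`, `k1`, `k2`) are
searched in log10 space over 1e-4..1e3 because fitted values span
orders of magnitude; delays (0-60 min) and `bn` (0 to the smallest
observed median) are searched linearly.  The lower bound of each
log-scale axis decodes to an exact zero, so switched-off pathways are
representable inside the search space; in particular a two-pathway fit
can be warm-started from a one-pathway result, which guarantees the
nested-model error ordering by elitism.

The optimizer is a (mu+lambda) evolution strategy: population 32,
elites 4, Gaussian mutation with sigma 0.25 log-units (linear axes:
sigma = 0.25 * range/4) annealed geometrically to 10% over 120
generations.  The error surface of the delayed model is multimodal, so
the search is repeated from 4 independent oversampled initial
populations (4x32 uniform draws, best 32 kept) and each restart's
champion is refined by bounded Nelder-Mead; the best refined candidate
is returned.  All draws come from one seeded generator
(`SeedSequence(seed).spawn`), making results exactly reproducible;
selection ties break by insertion order.  A fit of a six-point series
takes roughly a minute on one CPU at the default solver step.

Identifiability caveats, established on synthetic data: with only the
six study sampling times, (i) adding 10% independent multiplicative
noise to the medians makes `k1`, `k2` and `tr` unidentifiable — a local
refinement started at the generating parameters walks to distant values
while lowering the SSE — and (ii) even noise-free, the residual surface
has a (k1, tr) valley flat to machine precision, so point recovery from
six samples alone is ill-posed.  What the recovery tests therefore
exercise is the full study design: per-cell noise and per-sample
heterogeneity average into mostly *correlated* scale noise on the
pooled median time-course, under which the shape parameters are
recovered (median |log10 ratio| ≲ 0.2-0.3 for `k1`, `k2`; delay within
~4 min).  Denser sampling grids restore exact noise-free recovery.

## Assay statistics

Per-cell comet records are summarised per sample (patient x fraction),
per patient, or per fraction: median and quartiles by linear
interpolation (Tukey hinges would differ slightly; this convention is
fixed here), and a 95% percentile bootstrap CI of the median (2000
resamples, seeded; resampling operates on sorted values so summaries
are invariant to record order).  Differences from the pre-treatment
baseline are differences of group medians with a bootstrap CI and a
two-sided permutation p-value (10^4 label permutations on the median
difference, +1-corrected).  The permutation test replaces mixed-model
inference for the desk-scale pipeline; its type-I error at nominal 5%
calibrates to ~5-7% on Gamma-distributed null data.  Degenerate groups
(n = 1) get the point difference with CI and p flagged unavailable.
The pre-next-fraction sample keeps its own label and is never merged
with the pre-treatment baseline.

γH2AX focus counts above 10 per nucleus are recorded as 25 (foci merge
at early time-points and cannot be resolved; the replacement value is
the convention of the scoring protocol and is applied verbatim, with
"higher than 10" exclusive so a count of 10 is kept).  A cell is
"positive" at a configurable threshold of capped foci, 1 by default —
the positivity criterion is a documented package choice, not a
published definition.

## Synthetic cohorts

The generator emulates the study design: by default 6 patients, 3
fractions each, samples 15 min before and 15/30/60/120/360 min after a
6 Gy fraction, ~300 scored cells per sample.  Per-cell tail intensities
are Gamma distributed (right-skewed, positive; CV 0.6) around the model
observable scaled by mean-one lognormal patient (sigma 0.2) and
fraction (sigma 0.3) random effects — heterogeneity between fractions
of the same patient is a documented feature of such data, the specific
distributions are package choices.  2% of cells are replaced by draws
uniform in 60-100 %DNA, emulating sanguineous contamination and early
apoptotic cells.  Values are clipped to [0, 100]; at realistic means
the clipping bias is negligible.  Focus counts are Poisson with mean =
baseline rate (2.5 foci, the typical spontaneous level) + 0.6 x total
modelled damage, optionally low-pass filtered with a 60 min time
constant because foci decay more slowly than the comet signal; the mean
is tied to total damage because the model does not separate SSB from
DSB compartments.  All generators are pure functions of (inputs, seed).

What the synthetic data do **not** emulate: cell-cycle or oxygenation
effects, dose-rate dependence, apoptotic high-tail cells as a distinct
mechanism, inter-fraction carry-over of unrepaired damage, or any
image-level artefacts.  Passing recovery tests therefore show that the
pipeline is correct and well-conditioned under the assumed noise
structure, not that the model is identifiable on arbitrary patient
data.

## Known limitations

- The fitted constants of the delayed model are effective parameters;
  with a single dose rate the induction mode and `kcleav` scale are
  confounded, and the fast/slow labels carry no mechanistic pathway
  assignment.
- SSE over medians ignores the within-sample spread; quartile
  information is carried through pooling but not used as weights.
- No uncertainty quantification on fitted parameters (no profile
  likelihood or bootstrap CIs); the trace records convergence only.
- The brute-force grid oracle used in testing has 8 points per axis and
  bounds identical to the fit; it certifies optimizer quality, not
  global optimality.
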