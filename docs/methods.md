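# Methods

## The modelling problem

Six MS-medium components are varied over a box — KNO₃ and NH₄NO₃ at 0.5–2×
MS, the mesos salts at 0.5–2.5×, the micronutrients at 0.5–4×, BAP at
0.5–3 mg/l and IBA at 0.05–0.2 mg/l — and five growth responses (PR, SL,
STN, Vitri, QI) are measured per medium.  Three surrogate families map
composition → response: symbolic-regression models evolved by gene
expression programming (GEP), a Gaussian radial-basis-function network,
and a main-effects linear regression.  The best family is then optimized
over the box by a real-coded genetic algorithm to propose media.

## Experimental design

The experiments use a 6-factor, 3-level Box–Behnken design with 48 runs
and no center replicates: six cyclic blocks of three factors
({i, i+1, i+3} mod 6), each crossed over all eight ±1 sign combinations,
the remaining factors held at mid level.  `bbd_generate(6)` constructs this
design; the literal printed run order additionally ships as a fixture, and
the two agree run-for-run as coded multisets (a property the test suite
checks).  Mid levels are the range midpoints; the printed IBA mid level
0.13 is the rounding of 0.125, so coded↔actual matching uses a 0.01
tolerance.  The three control media (MS, WPM, QL) sit at 1× levels with
BAP 2.50 mg/l and IBA 0.20 mg/l.

## The published symbolic models and their transcription

The ten media equations (rootstock × response) are transcribed once, at
full printed precision, each as three addition-linked sub-expressions (the
three genes of the chromosome that evolved it).  Two transcription issues
required resolution, both settled *by testing against the printed data*,
not by re-fitting:

1. **Terminal mapping.**  The source's symbol legend (A = NH₄NO₃,
   B = KNO₃) contradicts its own data tables, which list KNO₃ first.
   Under A = KNO₃, B = NH₄NO₃ (data-column order) the structurally intact
   equations reproduce the reported fit quality (r² 0.93–0.97 against the
   48 designed media); under the legend's mapping they collapse
   (r² 0.06–0.88).  The package therefore uses the data-column order, and
   reads the optimal-media table's first two columns the same way.
2. **Protected operators.**  The printed equations leave the real domain
   inside the factor box (√ of a negative quantity, ln near 0, guarded
   divisions).  Conventions tried: √|x| (kept), clamp-to-zero, sign-
   preserving, and complex evaluation with a real-part read-out.  Only
   √|x| preserves the equations' fit to the data (e.g. Pyrodwarf PR falls
   from r² 0.90 to 0.12 under complex evaluation, to 0.52 under
   clamp-to-zero).  Full rules: √x = √|x|; odd roots sign-preserving; even
   roots on |x|; ln x = ln max(|x|, 1e−9); x/y and 1/x clamp |denominator|
   to ≥1e−9; exp clips its argument to ±50; every operator output is
   clipped to ±1e100.  All conventions remain selectable via
   `expressions.Convention`.

**Known defects of the printed equations.**  Five of the ten equations fit
the printed data at the reported level (Pyrodwarf STN/Vitri/QI, OHF
STN/Vitri).  The other five do not fit under *any* of the 720 factor
permutations or any operator convention (best r²: Pyrodwarf PR 0.90,
Pyrodwarf SL 0.38, OHF PR 0.01, OHF SL 0.04, OHF QI 0.21) and are
evidently corrupted in typesetting.  Consequences, all verified by direct
evaluation:

* The SL/STN/Vitri/QI optimal-media rows re-evaluate to their printed
  optima within ~0.05 (rounding of the printed compositions).
* The OHF PR equation cannot reach its printed optimum 9.42 anywhere in
  the box (supremum ≈ 6.3); it evaluates to 3.62 at the printed row.
* The Pyrodwarf PR equation contains 1/ln(avg(√((BAP−2.1016)/2), BAP)),
  which (i) is hypersensitive to the 2-decimal rounding of the printed
  composition (±0.4 over the rounding interval, value 14.16 vs printed
  13.00), and (ii) under the confirmed √|x| convention has a **pole inside
  the box**: the ln argument crosses 1 at BAP ≈ 1.4127, so the equation is
  unbounded there and a correct maximizer climbs to the guard ceiling
  rather than to 13.0.  Even restricting to the equation's natural domain
  (BAP ≥ 2.1016) the true maximum is ≈ 25.3 at the boundary, not 13.0: the
  printed optimum is not the global optimum of the printed equation.  The
  package optimizes the equations as printed and reports what it finds.

## The GEP engine

Fixed-length chromosomes of `n_genes` genes; each gene has a head of
length h (functions or terminals) and a tail of length t = h(a_max−1)+1
(terminals only), which makes every breadth-first open-reading-frame
decoding a complete tree.  Defaults follow the published run settings:
population 50, head 8, 3 genes linked by addition, mutation 0.044/symbol,
inversion 0.1, one-point/two-point/gene recombination 0.1/0.3/0.1, gene
transposition 0.1 (the source's once-mentioned "rotation" is implemented
as this operator).  Fitness is the root relative squared error
RRSE = √(Σ(P−O)²/Σ(O−Ō)²); selection is roulette on the strictly
decreasing transform (1000/(1+RRSE))^p with pressure exponent p (default
1, i.e. the plain documented transform; higher p sharpens selection).
Elitism defaults to 1.  Generations default to 500 with early stopping
when the best RRSE improves by <1e−6 over 50 generations; optionally,
stagnation for `reseed_stall` generations instead reseeds all non-elite
individuals (a diversity restart used by the noiseless recovery
experiment).  Ephemeral constants: the terminal alphabet may include a
slot "?" with one uniform[−10, 10] constant per gene position, perturbed
by jitter mutation; the original software's constant mechanism is
undocumented, so this is a deliberate design surface.  Whether the
printed equations are exactly expressible in a head-8, 3-gene genome is
unverifiable; the engine treats them as given output, not as decoding
test cases.

## RBF network

Y(x) = Σ W_j exp(−‖x−c_j‖²/(2σ_j²)) + b on standardized inputs (the
printed exponent is garbled; this is the standard Gaussian unit the text
describes).  The target is standardized internally and un-scaled at
prediction.  Centers initialize by k-means, widths by the nearest-center
distance, weights at zero and the bias at the target mean (so zero epochs
returns the initialization); all parameters then train by full-batch
gradient descent on the MSE (learning rate 0.05, 2000 epochs by default,
hidden units selectable from {5, 10, 15, 20} by held-out RMSE).  The
training-set hyperparameters are unpublished, so no attempt is made to
reproduce the source's RBFNN scores.

## Linear baseline, metrics, splitting

MLR is main-effects OLS (the source's own remark that the linear model
"could not explain" interaction effects confirms interactions were
absent); an optional quadratic/interaction expansion exists but is off by
default.  Metrics: RMSE, MARE (terms with O = 0 are excluded and
counted — STN/Vitri contain printed zeros where the formula is
undefined), MBE = mean(O−P), and Pearson r with r² alongside (the
source's "R²" formula is an unsquared correlation while its printed
values are consistent with r²).  The replicate-level 70/30 split
(510 → 357/153) uses uniform sampling without replacement, sizes
⌊N·f+0.5⌋, reproducible from an explicit seed; the source's own split is
unpublished, so its exact comparison table is out of reach and is
replaced by property checks (equation-vs-data fit; refit GEP out-ranking
MLR on synthetic replicates).

## Synthetic data

`spec_from_published` uses the five published equations of one rootstock
as ground truth; `generate_replicates` adds Gaussian noise per response
(default SD = 10 % of that response's printed range — replicate variance
is unpublished), clips to the response bounds (PR, SL ≥ 0; STN, Vitri ∈
[0, 100]; QI ∈ [1, 5]) and rounds PR to quarter-shoot resolution
(averaging counts over four explants per jar); at zero noise the
generator is exactly the identity on the (clipped) ground truth.  This
emulates the *statistical shape* of the experiment — design geometry,
replicate count, noise scale, bounded responses — not explant biology:
passing tests on it validate the pipeline's machinery, not any biological
claim.

## GA optimizer

Real-coded (one gene per factor), bounds from the experimental ranges
(BAP's design range 0.5–3 mg/l is used; one summary table prints 2.5 as
the upper limit but the design and reported optima use 3).  Defaults:
population 100, 200 generations, uniform crossover 0.9, per-gene Gaussian
mutation 0.1 with SD 10 % of the factor range clipped to bounds, elitism
2, 10 restarts (restart r is seeded seed+r), roulette selection on rank
weights — rank weighting handles minimization and negative objectives
without the pathologies of raw fitness-proportional selection.  The
returned best value is always the objective re-evaluated at the returned
point, and the engine is checked against an analytic 6-D optimum and an
11-points-per-axis exhaustive grid.  QI optimization rows carry a
metadata note: the source's prose attributes its QI optima to the RBF
models while the table caption says GEP; the package optimizes the
published equations and flags the ambiguity.

## Problem sizes used by the shipped checks

The test suite and acceptance script run at the study's native scale:
48-run design, 51-media datasets, 510 synthetic replicates with a 357/153
split, 10-seed recovery and GA experiments, a 1.77M-point grid oracle,
10k-draw totality fuzzing.  The one deliberate reduction is the GEP refit
used in the model-ranking property (population 120, ≤200 generations,
reduced function set), chosen as a comfortable budget for that check's
purpose — demonstrating that a fresh symbolic fit out-ranks the linear
baseline — rather than squeezing out the last decimals of fit.

## Known limitations

* Five printed equations are typeset-corrupted (above); the affected
  reported optima (both PR rows) and the GA-search reproduction of the
  Pyrodwarf PR optimum are therefore not recoverable from the printed
  source, and the corresponding acceptance checks fail by design, honestly.
* The replicate-level raw data and the original random split are
  unpublished; the source's model-comparison table is reproduced only as
  qualitative ordering properties.
* Protected-operator conventions are a modelling choice; all evaluations
  are conditional on the √|x| family documented above.
* The synthetic generator's Gaussian, independently-noised replicates
  ignore jar-level correlation and count-valued responses beyond the
  quarter-shoot rounding.
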