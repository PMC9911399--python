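# Methods

`hitseq` models a sequencing-based equilibrium binding experiment
("HiTS-Eq"): a pool of RNAs carrying every possible 7-mer in a randomized
window is equilibrated with an RNA-binding protein at a series of
concentrations, the **unbound** fraction is recovered and sequenced, and the
depletion of each variant from the free pool reports its apparent affinity.
This note documents the model, the estimators, the synthetic-data generator,
and the numerical choices, in that order.

## Equilibrium model

Binding is treated as pseudo-first-order: total protein (up to ~20 µM) vastly
exceeds the total RNA pool (1 nM spread over 16,384 species), so free protein
≈ total protein `E` and the free fraction of variant v is

    f_v(E) = Kd_v / (Kd_v + E).

For two species the free-pool ratio follows the competitive-binding form

    S1/S2 = (S1,0/S2,0) · (1 + E/K2) / (1 + E/K1),

with `S,0` the no-protein control amounts.  Solving for the variant's
constant with `E` expressed in units of the reference K_1/2 (`E' = E/K1`)
gives the per-concentration estimator implemented in
`affinity.relative_affinity`:

    K_A,rel(v) = (R·(1 + E') − 1) / E',   R = n_ref(E) / n_v(E),

where `n` is the control-normalised read frequency.  Reported `K_A,rel` is a
relative **association** constant: the reference (cognate 7-mer `UGCAUGU`) is
exactly 1 and higher affinity means a larger value.  On exact free-fraction
inputs this inversion returns `Kd_ref/Kd_v` to machine precision at every
informative concentration, independent of `E` — the property the unit tests
pin against a brute-force equilibrium oracle.

Note on the printed inversion formula in the source literature for this assay
family: solving the ratio equation for K2 requires the control ratio
`S2,0/S1,0`; the form with `S1,0/S2,0` is algebraically inconsistent with the
ratio equation and is treated here as a typographical inversion.  The
implementation uses the consistent form, verified against the oracle.

## Estimators across concentrations

Three estimators aggregate the concentration series:

* **median** (default) / **mean** — of the per-concentration inversions,
  dropping concentrations whose numerator `R·(1+E') − 1` is nonpositive
  (no measurable depletion relative to the reference).  Variants with no
  informative concentration are flagged `below_detection` with value 0.
* **global-fit** — a per-variant Poisson maximum-likelihood fit of the whole
  depletion curve on raw counts.  The expected count of variant v at
  concentration E is

      µ_vE = a_v · t_E · f_v(E) / P(E),

  with `a_v` the control exposure, `t_E` the library depth ratio, and
  `P(E) = mean_v f_v(E)` the pool-renormalisation factor (sequencing depth is
  fixed per library, so depleting strong binders enriches everything else).
  `Kd_v` is profiled on a 500-point log grid with parabolic refinement; the
  shared `P(E)` profile is pinned by its equimolar-pool self-consistency
  condition and solved with an Anderson-accelerated fixed point (plain
  alternation stalls on a near-neutral mode between the profile and the bulk
  Kd scale).  With the known equimolar exposure `depth/16384` the estimator
  reaches the Cramér–Rao bound of the counting experiment.

The median estimator is exact on noise-free data but degrades on sampled
reads wherever the **reference variant itself** is depleted out of the free
pool: above ~100 nM the cognate reference drops below one expected read per
library, and per-concentration ratios to it become noise precisely at the
concentrations where weak binders carry their signal.  The global fit does
not use per-concentration reference counts at all and is the right tool for
deep quantitative runs; it is also exactly invariant to the `ref_k_half`
setting (the unit cancels), whereas the median estimator's output moves with
a twofold `ref_k_half` perturbation by more than 1% outside the strong-binder
regime.

## Isotherm fits

Individual titrations use the quadratic (ligand-depletion) isotherm

    FB = A · [(K + R0 + P0) − sqrt((K + R0 + P0)² − 4·R0·P0)] / (2·R0)

and competition experiments

    FB = A · R1 / (R1 + K1·(1 + R2/K2)),

fit by `scipy.optimize.curve_fit` with multistart initialisation (K at 0.1×,
1×, 10× the titrant midpoint; A at 1).  As `R0 → 0` the quadratic form
reduces to the hyperbola with half-saturation at `P0 = K_1/2`; at `R2 = 0`
the competition form equals the no-competitor isotherm.  Both limits are
asserted in tests.

## Synthetic-data generator

The generator emulates the study conditions end to end:

* **Construct** (RNA): `GGGAGACCGGAAUUCAGAUUGUCC-N7-UUAAAUCCCGUCGUAGCCACCA`;
  reads are DNA, 50 nt: 2-nt UMI, 3-nt index barcode (`ATC GAT CGA TCC CAC
  TGT ACT GTA`), the 24-nt constant region, the 7-mer, then the 3' constant
  prefix.
* **Landscape**: all 16,384 7-mers with Kd drawn from a two-component
  log-normal — variants containing `GCAUG` from a cognate mode
  (median 3 nM, σ_ln = 0.7) and all others from a background mode
  (median 8 µM, σ_ln = 1.0).  The medians bracket the reported cognate
  K_1/2 (1.6 nM) and the >17 µM bound for a single-substitution variant;
  the separation reproduces the strongly bimodal affinity distribution of a
  highly specific RNA-binding domain.  An alternative generator produces
  Kd additively from per-position coefficients plus optional pairwise
  couplings, for model-recovery tests with exactly known ground truth.
* **Concentrations**: 0 (control) plus 7 log-spaced points from 2 nM to
  19,740 nM, the top concentration used in the emulated experiment.
* **Reads**: per library, `depth` molecules are drawn multinomially from the
  exact unbound composition (default 10⁶; the real study's depth is not
  published), each gets a random UMI and the library index, is duplicated a
  geometric number of times (mean `pcr_duplication`, the simplest
  overdispersion that exercises UMI collapse) and receives independent
  per-base substitution errors (default 10⁻³, typical Illumina scale).

What the generator does **not** emulate: RNA secondary structure and
adapter-masking failures, reverse-transcription and gel-purification biases,
index hopping, quality-score structure (a fixed quality string is written).
Passing tests therefore demonstrate the correctness of the analysis chain
under the stated statistical model, not robustness to these real-data
artefacts.  The default bimodal background is positionally unstructured by
design (it reproduces the affinity *distribution*, not the additive
structure real binding energies show), so variance-explained statistics of
PWM/PWC fits on the default landscape are near zero; model-quality metrics
are meaningful on the additive generator, and the acceptance script computes
them there.

## Read processing

Reads shorter than 36 nt are rejected (`too_short`); the constant region
(read positions 6–29, 1-based) must match within Hamming distance 1, no gaps
(`constant_mismatch` otherwise); the 7-mer is taken verbatim — substitution
errors inside the randomized window are undetectable in principle and are
quantified in simulation instead (~0.7% of reads migrate to a neighbouring
variant at error rate 10⁻³).  Demultiplexing is by exact 3-nt index match.
Counting reports both raw accepted-read counts and UMI-collapsed counts
(distinct `(UMI, 7-mer)` pairs per library).  With 2-nt UMIs only 16 exist,
so collapsed counts saturate at 16 per (library, variant) cell — a warning
fires when cells hit the ceiling, and deep libraries should be quantified
from raw counts with PCR-duplication-free simulation settings.
Normalisation adds a 0.5 pseudocount to every cell, converts to per-library
frequencies and divides by the control frequency; values < 1 mean depletion.

## 5-mer aggregation

Each 7-mer carries three 5-mer registers.  A 5-mer's contexts are the
distinct 7-mers containing it at offsets 0–2: 48 for non-self-overlapping
5-mers (3 offsets × 16 flank pairs), fewer for self-overlapping ones
(40 for `AAAAA`).  Summaries use box-plot semantics — median (default; the
value that feeds the regression models) or mean, quartiles, min/max
whiskers.  Registers extending into the fixed linkers are excluded, which is
what makes the context count 48.  Flanking-base effects use the unambiguous
centred register `N-core-N` (16 heptamers), grouped by either flank, with
pairwise log-ratio matrices between flank choices.

## Binding models

`ln(K_A,rel)` is regressed on indicator features under reference coding: the
cognate sequence (`GCAUG` for 5-mers, `UGCAUGU` for 7-mers) sets the
reference level, so its nucleotides carry coefficient 0 and every
coefficient reads as the ln-affinity change of a substitution away from the
consensus (negative = destabilising).  "Used as baseline and excluded" is
implemented as two rules: reference coding, **and** withholding the cognate
variant's data point from the fit — its out-of-fit residual then measures
how far the consensus sits above the additive expectation, the signature of
a distinct cognate binding mode.  An intercept is included by default (the
baseline-encoded row need not have ln value 0 for 5-mer medians);
`r2` is reported on the fitted set, and `r2_with_baseline` including the
withheld point, since either convention is defensible.  The pairwise model
adds one coefficient per position pair and non-baseline nucleotide pair
(10 × 9 = 90 for 5-mers, 105 columns with the positional terms); couplings
with |t| > 3.5 from the OLS standard errors are flagged significant, with no
multiple-testing correction (the bare threshold is this model family's
convention).  Values below the detection floor (default 10⁻⁴) are clipped
before the log; with zero residual variance t-statistics are set to 0
(ratios of rounding error otherwise).  OLS, standard errors and t-values
come from `statsmodels`.

## Distribution analytics

* Histograms: 100 equal-width bins over `[0, max K_A,rel]` ("bin size 100"
  is read as a bin *count* — a width of 100 is impossible for values ≤ 1).
* Bimodality: one- vs two-component Gaussian mixtures on floored
  `ln(K_A,rel)` compared by BIC (`scikit-learn`).  Because the high-affinity
  mode holds only ~0.3% of variants, k-means initialisation tends to split
  the broad background; an additional bulk-vs-top-1% initialisation is tried
  and the better-likelihood fit kept.  The minor component's membership is
  reported — on a well-separated landscape it contains every `GCAUG`
  variant.
* Logos: position frequency matrices and information content
  `2 + Σ p log2 p` bits from the top-N variants (default 40), ties broken
  lexicographically.  No motif-discovery E-values are computed.
* Percentiles use the midrank convention for ties.
* RBNS R scores map onto [0, 1] via linear rescaling onto [1, e] followed by
  the natural log — strictly monotone with min → 0, max → 1.
* The specificity ratio is max/median of normalised affinities; it is scale
  invariant and reported on the max-normalised `K_A,rel` distribution.

## Problem sizes and defaults

The end-to-end recovery check simulates 8 libraries × 10⁶ reads at error
rate 10⁻³ and recovers ln K_A,rel with Pearson r ≈ 0.98 against ground truth
over variants whose Kd lies between the smallest and largest nonzero
concentrations (the informative range); outside that range depletion curves
are flat and no estimator can place a variant beyond flagging it.  The
acceptance script (`scripts/acceptance.py`) re-runs the same pipeline at
those sizes in about a minute.  Model-recovery tests run 20 seeded noisy
replicates at σ = 0.1 on 1,024 5-mers.

## Known limitations

* Absolute calibration is out of scope: the assay yields relative constants;
  `ref_k_half` only sets units for the median estimator and cancels in the
  global fit.
* The global-fit estimator assumes an equimolar initial pool when using the
  known exposure (`equal_pool=True`); for real pools with synthesis bias set
  `equal_pool=False` to fall back to observed control exposures at roughly
  √2 the estimation error.
* UMI error correction is deliberately absent (16 possible UMIs make
  networks meaningless) and quality scores are ignored.
* Couplings beyond pairwise, regularised/Bayesian fits, and kinetic
  (on/off-rate) modelling are out of scope.
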