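# Methods

## Genotype state space and IBD kinship

An autopolyploid of even ploidy *m* under random bivalent pairing
transmits gametes that are size-*m*/2 subsets of its *m* labeled
homologs, each equally likely; a full-sib cross therefore segregates
*p* = C(*m*, *m*/2)² ordered genotype classes. Parent-A homologs are
indexed 0..*m*−1 (displayed `a..f` for hexaploids), parent-B homologs
*m*..2*m*−1 (`g..l`); gametes are enumerated lexicographically and
states row-major over (parent-A gamete, parent-B gamete), which fixes
the `state_index` used in all files and matrices.

The genotype-relationship matrix **Π** has entries
Π_jj′ = |shared homolog labels| / *m*, taking the *m* + 1 values
{0, 1/*m*, …, 1}. Writing **S** for the *p* × 2*m* binary state-by-homolog
incidence matrix, **Π** = **S S**′/*m* exactly. Consequently the kinship
kernel at a map position, **G** = **Z Π Z**′, factors as
**G** = **X X**′/*m* with **X** = **Z S** the *n* × 2*m* matrix of homolog
inclusion probabilities ("dosages"). Every heavy computation in the
package — kinship, REML, score scans, FEIM designs — works through **X**
and never materializes a *p* × *p* or position-wise *n* × *n* product it
does not need; the equality with the naive double sum over p² genotype
pairs is asserted to 1e−10 in the tests. Probability rows must sum to 1
within 1e−6 (then renormalized); near-zero upstream probabilities are
accepted as-is. Double reduction and preferential pairing are out of
scope throughout.

## Meiosis and trait simulator

The generator defines the study conditions for all replicated
experiments. Each meiosis draws a uniform random perfect matching of the
*m* homologs into bivalents, independently per parent, per individual
and per chromosome. Along a chromosome each bivalent transmits one of
its two homologs following a two-state Markov chain with switch
probability r(d) = (1 − e^(−2d/100))/2 per interval of d cM (Haldane, no
interference). Offspring states are recorded one-hot; an optional
softening mixes rows with the uniform distribution to mimic HMM
uncertainty (default 0).

Traits are built exactly as the mapping model assumes: per QTL,
**g**_q ~ N(**0**, **G**_q σ²_q) drawn through a symmetric
eigen-factorization with 1e−8 diagonal jitter, plus N(0, σ²) noise; the
error vector is stored so "offset" analyses can subtract it. Default
study conditions: ploidy 6, *n* = 298 offspring, 3 linkage groups ×
120 cM with a 2 cM grid, QTL variances {0.75, 0.50, 0.25} against
residual 1 (heritabilities 0.3/0.2/0.1), population mean 0. Scenarios:
*unlinked* (QTL on three distinct LGs), *random* (uniform positions,
≥20 cM apart when sharing an LG), *linked* (two QTL on one LG ≥50 cM
apart; the third on a different LG). Simulated QTL snap to grid
positions. One simulated population is shared by all trait replicates of
a study, mirroring the reuse of a single mapping population. A single
integer seed fans out to independent streams via `SeedSequence.spawn`.

What the simulator does **not** emulate: genotyping error and dosage
miscalls, real HMM probability profiles (information decays between
markers), segregation distortion, multivalent pairing, epistasis and
QTL×E. Passing tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not robustness to violations of them.

## REML and the score test

With variance ratios τ_q = σ²_q/σ², V(τ) = Σ τ_q G_q + I. An
orthonormal error-contrast basis **A** ((n−1) × n, **A1** = 0,
**AA**′ = **I**; Helmert construction, invariance to the basis is
tested) removes μ, and profiling removes σ², leaving
ℓ(τ) ∝ −½{ñ log(ỹ′Ṽ⁻¹ỹ) + log|Ṽ|}. REML maximizes ℓ over τ ≥ 0 with
L-BFGS-B and analytic gradients, multi-started at τ ∈ {0.01, 0.5, 2}
(plus a warm start during searches), τ clamped at 0, σ̂² = ỹ′Ṽ⁻¹ỹ/ñ and
μ̂ by GLS. Because every kernel is rank ≤ 2*m*, all REML objective and
scan computations are pushed through Woodbury identities into the
(2*m*·Q)-dimensional inner space; fits and whole-genome scans cost
small-matrix operations per position regardless of *n*, and equality
with the dense-matrix path is covered by tests.

The score statistic for kernel *r* at the null (τ_r = 0, nuisance τ̂
from REML) is the derivative of ℓ; under normality,
S_r > s ⟺ Σ_i (λ_i − c) z²_i > 0 with λ_i the eigenvalues of
Ṽ₀^{−1/2} G̃_r Ṽ₀^{−1/2}, z_i iid N(0,1), and c the observed
quadratic-form ratio. Tail probabilities:

* **exact** (single kernel, no nuisance): characteristic-function
  inversion with an Imhof-type integrand, evaluated by vectorized
  composite Simpson with embedded error control (target 1e−10,
  truncation where the integrand's envelope falls below e^(−45)); when
  the result is more extreme than 1e−7 a Lugannani–Rice saddlepoint
  evaluation takes over (the oscillatory integral loses absolute
  precision there); a 2×10⁵-draw Monte-Carlo fallback guards numerical
  failure.
* **moment** (nuisance QTL present): the null quadratic form at the
  plugged-in τ̂ is matched to a scaled-shifted chi-square a·χ²_g + b via
  its first three cumulants (κ₁ = Σλ′, κ₂ = 2Σλ′², κ₃ = 8Σλ′³, with
  negative-skew cases handled by reflection). The approximation is
  validated against Monte Carlo in the test suite rather than assumed.

P-values are floored at 1e−16 so LOP = −log₁₀P stays finite.

## Thresholds, model search, support intervals

Genome-wide significance is calibrated by score-based resampling:
standard-normal phenotypes are scanned under the no-QTL null, the
P-value of each resample's top score is stored, and the level-α
threshold is the α-quantile of these genome-wide minima — so a null
genome scan crosses it with probability α (the calibration is itself
tested). Default N = 1000 resamples for real analyses; the scaled
studies use N = 200.

Search proceeds as: (1) forward search — add the minimum-P position
outside 20 cM windows around current QTL while P beats the permissive
threshold (α = 0.20), re-estimating nuisance τ each round; (2) model
optimization — in entry order, re-scan each QTL genome-wide (excluding
the other QTL's windows) and move it to the minimum-P position, then
backward-eliminate the worst QTL failing the stringent threshold
(α = 0.05), one per round, iterating until stable, with cycle detection
on the visited models; optionally repeat forward search at the stringent
threshold until nothing is added or dropped; (3) profiling — score
statistics at every position conditional on the final model, where the
conditioning set at a position drops any model QTL within the window, so
each QTL's own neighborhood is profiled without itself. Ties in minimum
P break to the lowest LG, then lowest cM.

Support intervals are the maximal contiguous grid region around a peak
with LOP ≥ peak − d (default d = 1.5, ≈95% empirical coverage), clipped
at LG boundaries. Intervals are anchored at the profile's contiguous
local maximum around the fitted position (hill-climbing), since REML
refinement and the conditional profile can disagree by a grid step.

FEIM, the single-QTL comparator, regresses y on the 2*m* − 2 retained
homolog-dosage columns (the first homolog of each parent is dropped;
each parent's columns sum to *m*/2). The test is Gaussian **ML** (not
REML): LRT = n ln(RSS₀/RSS₁), LOD = LRT/(2 ln 10) — chosen because the
closed form admits an exact least-squares oracle; rank-deficient designs
fall back to the pseudoinverse. Genome-wide thresholds come from
phenotype permutations (designs fixed, one shared permutation set per
replicate); peaks are called greedily above the threshold with the same
20 cM exclusion window as the search, so FEIM/REMIM comparisons share
their bookkeeping. Missing phenotypes are dropped listwise.

## QTL characterization

h²_q = σ̂²_q / (Σ σ̂²_q + σ̂²) — the plain variance-component ratio, no
kinship-diagonal correction. BLUPs:
**û**_q = σ̂²_q **Π Z**′_q **V̂**⁻¹(**y** − **1**μ̂) computed through
**Π Z**′ = **S X**′/*m*; **ĝ**_q = **Z**_q**û**_q; Σ û_q = 0 and the
equality of the two BLUP routes hold to 1e−8 (tested). Additive allele
effects are unweighted means of û over the p/2 states carrying each
homolog (centering would be a no-op given the zero-sum property);
within-parent effects sum to zero. Breeding values are per-individual
sums of ĝ_q over QTL.

## Replicated study and its scoring

Mapped QTL are classified per replicate: *paired* if <20 cM from an
unclaimed simulated QTL on the same LG (greedy in ascending P; the
smaller-P call wins a contested simulated QTL); *matched* if the support
interval contains a simulated position; *mismatched* otherwise. Power =
matched/simulated, FDR = mismatched/mapped, precision = mean |Δposition|
of paired calls, coverage = matched/paired. The replicated studies in
the tests and the acceptance script use 100 replicates (40 for the
two-method linked comparison) at the default study conditions above —
sizes chosen to keep a desk run in minutes while leaving the binomial
error of the reported rates a few percentage points. In the simulation
studies REMIM runs one forward round plus model optimization (no
repeated forward phase), matching how the replicated experiments are
defined; the full repeat-until-stable loop is the default for real
analyses.

## Known limitations

* The moment-based null P-value with nuisance QTL is an approximation;
  extremely small conditional P-values inherit its (Monte-Carlo-gated)
  accuracy, and the 1e−16 floor caps LOP at 16.
* Score tests assume Gaussian phenotypes; heavy-tailed traits will
  distort both the exact and the resampled null.
* FEIM power/FDR on small maps is sensitive to the shoulder structure of
  LOD profiles: broad peaks can exceed the threshold beyond the 20 cM
  exclusion window and are counted as false discoveries, a behavior
  inherent to single-QTL scanning rather than a defect of the
  bookkeeping.
* No epistasis, QTL×environment, multi-trait covariance, multi-parental
  designs, or multivalent pairing / double reduction; the
  multi-environment mixed model behind the H² utility is fitted
  externally — only the entry-mean H² ratio with harmonic-mean
  replication is computed here.
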