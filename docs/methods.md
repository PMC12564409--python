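# Methods

This note records the statistical model behind `segdist`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions, at the level of detail a user would
need to judge or extend the package.

## 1. Entropic segmentation

A DNA sequence S of length N over {A, C, G, T} is scanned at every
admissible cut position i; the Jensen–Shannon divergence between the flank
base-frequency vectors,

d(i) = H(S) − (n₁/N) H(S₁) − (n₂/N) H(S₂),    H(·) in bits,

is maximised over i.  The cut is accepted when the maximum is statistically
incompatible with a homogeneous i.i.d. sequence of the same length, and the
procedure recurses into both flanks, each tested at its *own* length.  The
recursion stops where no significant cut remains; the segments tile the
sequence exactly.  The significance level s (default 0.95, i.e. p₀ = 0.05)
is the single resolution knob: higher s yields fewer, longer, more
conservative segments.

**Null distribution.**  The distribution of max_i d(i) under the i.i.d.
null has no closed form we are willing to hard-code, so it is estimated by
Monte-Carlo: for each length on a powers-of-two grid, `n_sims` i.i.d.
sequences are simulated (symbol probabilities either uniform or estimated
from the data under study — the default in `landscape_pipeline`), the
maximum divergence of each is recorded, and the empirical CDF is
interpolated linearly in log N between grid points.  Tables are
deterministic given (seed, grid), independent of grid order, and persist as
plain text.  `n_sims` may be a per-length schedule; the default schedule
spends 400 simulations per grid point up to 2¹⁷ and a quarter of that
above, since each simulation costs O(N).

**Search strategy.**  Below 16,384 bp the maximisation is exhaustive.
Above it, a coarse scan with stride ⌈N/8192⌉ is refined exhaustively within
±2 strides of the coarse optimum.  Because |d(i+1) − d(i)| = O(log N / N),
the approximation error is far below the null's quantile spacing; crucially
the null simulation applies the *identical* search, so the test remains
calibrated against its own statistic (verified empirically: the type-I
error at s = 0.95 over 1,000 i.i.d. sequences of length 10⁴ is ≈ 0.04).

**Conventions.**  Coordinates are 0-based half-open.  Ambiguity codes
(including N) occupy coordinates but contribute to no counts; flank weights
use unambiguous counts.  Ties in the profile break to the leftmost
position.  Cuts on subsequences shorter than the calibrated grid minimum
(8 bp) are never attempted; sequences longer than the grid maximum raise an
explicit error rather than extrapolating.  Runs of ≥ `min_gap` (default 10)
N symbols are treated as assembly gaps and split contigs before
segmentation.  The default alphabet is the four-letter one; a binary mode
first maps bases through a grouping (SW/RY/KM) and segments the two-letter
sequence with a k = 2 null.

**Optimal reference.**  `optimal_segmentation_dp` maximises the same
objective, J = H(S) − Σ (n_j/N) H(S_j), globally for a fixed number of cuts
by O(N²) dynamic programming.  It exists to validate the heuristic (for one
cut the two coincide exactly) and is deliberately capped to short
sequences.

## 2. Landscapes and the distance

Each segment with at least one unambiguous base contributes its grouping
fraction (G+C, A+G or G+T) once — not weighted by length, so long and short
homogeneous domains carry equal weight in the signature; a length-weighted
variant exists but is off by default.  Fractions are binned into n = 50
equal-width bins fixed on [0, 1] (left-closed; the last bin closed at 1),
so histograms from different genomes share support.  Bin edges are computed
as i/n so that decimal fractions land in the intuitive bin.

The Segment Compositional Distance is D = √JSD(P, Q) with logarithms base
2.  The square root is the default because it satisfies the triangle
inequality (property-tested over 10,000 random histogram triples) while raw
JSD does not in general; `mode="raw"` gives the plain divergence, and the
two agree at the printed endpoints 0 and 1.  Empty bins need no
pseudocounts (0 log 0 = 0 exactly).

**Sampling floor.**  Two genomes drawn from the *same* landscape model do
not sit at D = 0: with m segments spread over K occupied bins, the expected
JSD between the two empirical histograms is ≈ (K − 1)/(2 m ln 2), i.e. a
floor of D ≈ √((K−1)/(2 m ln 2)) — about 0.12 at m = 1000 and K ≈ 20.
This floor, not the drift signal, sets the minimum genome size at which
group structure is resolvable; the simulation studies below choose their
genome sizes from it.

## 3. Comparative layer

- **Within/between groups:** unordered taxon pairs are partitioned by
  shared group label; one-sided Mann–Whitney U and Welch t tests (within <
  between) are reported raw, without multiplicity correction.
- **Divergence times:** Pearson and Spearman correlations of D against ΔT,
  over all pairs or restricted to pairs anchored on a reference taxon.
  Constant inputs are reported as undefined rather than NaN.
- **Trait axis:** classical (Torgerson) principal coordinates of the
  squared-distance matrix; the leading eigenvector scaled by √λ₁, sign
  fixed by the first taxon.  Chosen over stress-minimising MDS because it
  is deterministic and all downstream indices are invariant to affine trait
  transforms (asserted in tests).  A two-taxon matrix is handled as ±D/2.
- **Signal indices:**
  - *Moran's I* with row-standardised 1/patristic-distance weights
    (documented explicitly because reference software rarely states its
    default); permutation expectation −1/(n−1).
  - *Abouheif's C*<sub>mean</sub>: the same autocorrelation with the
    Abouheif proximity matrix, A_ij = 1/Π(#direct descendants) over
    internal nodes on the tip-to-tip path, row-standardised, zero diagonal.
  - *Blomberg's K*: observed MSE₀/MSE over its Brownian expectation, with
    the phylogenetic GLS mean; *K\** is the variant standardised about the
    arithmetic mean (expectation (tr V − ΣV/n)/(n−1)) — the literature does
    not pin the formula down, so this package's reading is stated here.
    Both ≈ 1 under Brownian motion (mean over 500 replicates on a 32-tip
    pure-birth tree lies in [0.85, 1.15]).
  - *Pagel's λ*: ML over [0, λ_max] where λ_max is the positive-definiteness
    boundary of the transformed covariance (not capped at 1; time-calibrated
    trees admit λ slightly above 1).  λ̂ agrees with an independent R
    implementation to four decimals on shared fixtures.
  - Permutation tests use B = 999 by default with p = (b+1)/(B+1), so p is
    never exactly zero and is exact-level under exchangeability.  The λ
    p-value is instead the likelihood-ratio test against λ = 0 with a
    boundary-halved χ²₁; this test is *conservative* at realistic tree
    sizes (empirical size ≈ 0.01 at the nominal 0.05 for 32–128 tips, a
    behaviour shared by reference implementations) — a known limitation,
    reported as such rather than silently replaced by a permutation test.
- **Trees:** UPGMA is implemented directly (merge heights D/2; ties broken
  toward the pair containing the lexicographically smallest member label,
  making output deterministic); neighbor joining delegates to scikit-bio
  with negative branches clamped to zero.  Newick I/O preserves underscored
  labels.

## 4. Synthetic data generator

The generator emulates exactly the two properties of real genomes the
method consumes: genomes are concatenations of compositionally homogeneous
segments, and landscapes diverge with separation time.

**Landscape model.**  Segment lengths are log-normal (mean 2.5 kb, log-sd
0.6 by default; a geometric law is available but produces many sub-500 bp
micro-segments that no significance test can detect).  Per-segment G+C is
drawn from a mixture of 24 narrow beta families (means spanning 0.22–0.72,
concentration 1200, smooth unimodal abundance profile) — an isochore-family
caricature.  RY and KM fractions are tight betas centred on 0.5, per
Chargaff's second rule; segment base probabilities follow from (gc, ry, km)
in closed form, clipped at 10⁻⁴ and renormalised in the rare infeasible
draw.  Genomes are packed into `n_contigs` equal contigs (default 8), both
for realism and so the null grid never needs to exceed 2²⁰.

**Why 24 families?**  The number of *independently evolvable degrees of
freedom* of a landscape is capped by the number of occupied histogram bins.
With few families, the distance between two lineages is dominated by a
handful of Brownian draws and its coefficient of variation at fixed ΔT is
~0.5, which destroys the rank correlation between D and time regardless of
genome size.  Spreading the landscape over many distinguishable families
(and letting family *abundances* drift as well as their means) pushes the
effective dof toward the bin-resolution ceiling and brings the CV down to
~0.1.  This is the single most consequential design choice in the
generator.

**Drift.**  Along a guide tree, each family's logit-mean performs Brownian
motion with σ = 0.006 per √My, each family's log-abundance with 6σ, and
the RY/KM logit-means with 0.25σ.  Segment boundaries are redrawn
independently per tip (the landscape is invariant to where segments sit;
the `boundary_resample_fraction` field records this design point).  With
these defaults, lineages ~100 My apart differ visibly in family abundances
and by a few percentage points in family G+C — comparable to the contrast
between mammalian orders.

**What the generator does not emulate:** substitution processes (no
JC/GTR), indels and rearrangements, repeats, long-range correlation within
segments, ambiguity-code structure of real assemblies.  Passing tests
therefore demonstrate that the *pipeline* recovers the compositional-drift
signal it is designed for; they do not certify performance on real
assemblies, where segment structure is richer and drift is not Brownian.

**Guide trees.**  Deterministic ladders (`ladder_tree`, log-spaced depths —
the sampling structure of a reference species plus relatives at graded
distances), clade trees with controllable depths, Kingman coalescent and
Yule trees, and a 42-tip ultrametric tree anchored on the bundled
human-vs-mammals divergence-time table (within-group splits of that tree
are synthetic and marked as such).  On topologies where most pairs share a
few deep branches (pure-birth, coalescent), the D-vs-ΔT rank correlation
is intrinsically weakened by shared drift realizations; simulation studies
that probe the time signal therefore use the ladder design.

## 5. Problem sizes used by the test suite

The validation suite runs the paper-scale statistical studies at sizes
chosen from the sampling-floor formula of §2, as this package's own study
conditions: type-I calibration at N = 10⁴ over 1,000 replicates;
change-point recovery on 100 kb two-block genomes (ΔGC = 0.2, 100
replicates); the divergence-time study on three replicate 20-taxon ladder
radiations with 4 Mb genomes (4 contigs, 4 kb mean segments, ≈ 900
detected segments per genome), reporting the median all-pairs Spearman;
group contrasts on a 12-taxon three-clade radiation with 1 Mb genomes; and
full-pipeline clade recovery (UPGMA monophyly) over 50 replicate 6-taxon
radiations with 3 Mb genomes.  Signal-index calibration uses 32-tip trees
(500 replicates) and λ recovery 128-tip trees (200 replicates).

## 6. Known limitations

- The Monte-Carlo null assumes i.i.d. composition within a homogeneous
  region; long-range correlated sequence inflates segment counts.
- The λ likelihood-ratio p-value is conservative (see §3); its point
  estimate is unaffected.
- Landscapes from genomes with very few segments (small m) carry a large
  sampling floor; distances between such genomes are upward-biased, and
  many-bin histograms make this worse — prefer n = 50 bins unless m is in
  the thousands.
- D saturates at 1 once landscapes are disjoint; beyond that point deeper
  divergence is invisible to the method.
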