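# Methods

## Scope and data model

The package analyses a biparental RIL population genotyped on a
recombination-bin map: adjacent SNPs with identical segregation are merged
into bins, each bin acting as a single fully informative marker with two
homozygous classes (parent-1 `A`, parent-2 `B`; heterozygous and missing
calls are tolerated in input and excluded pairwise).  All coordinates are
stored in base pairs on 1-based closed intervals; megabases appear only in
written tables (Mb = bp / 10⁶).  E-traits are log2-scale expression values
with one genomic anchor per probe set — the midpoint of the annotated locus
— so a gene measured by several probe sets keeps one anchor per probe set.
E-traits without a locus anchor are excluded from cis/trans classification
and reported separately.

## The scan

Composite interval mapping is implemented as Haley–Knott-style regression:
on a sequencing-derived bin map the genotypes are effectively fully
informative, so the interval-mapping mixture likelihood collapses to least
squares and LOD(b) = (n/2)·log₁₀(RSS_reduced/RSS_full).  Scan positions are
the bins themselves; the map is already ultra-dense, so pseudomarkers
between bins would add nothing.  Covariates (default 5) are chosen by
greedy forward least squares; at each test position, covariates within half
the scan window (default 10 cM, genetic distance, same chromosome) are
dropped from both the full and the reduced model.  Bins with no residual
genotype variance score LOD 0 with a warning; a constant trait scores 0
everywhere.  The implementation groups test bins by their retained
covariate set and residualizes once per group, which makes a genome scan a
handful of matrix products.

Permutation thresholds follow the global scheme: sample `perm_sample_size`
e-traits (default 100), permute the line labels of each `n_perm` times
(default 1000), rescan, and pool all genome-wide maxima; the threshold is
the (1 − α) pooled quantile.  Covariates are re-selected inside every
permutation replicate by default (conservative — the permuted trait gets
the same selection opportunity as the observed one); this is configurable
off for speed.  Whether the original analysis pooled 1000 permutations per
sampled e-trait or in total is ambiguous; pooling per e-trait is the
implemented reading, and the default declaration thresholds (LOD 4.95 for
expression, 5.0 for phenotypes) are taken as given for full-scale runs.

Support intervals walk outward from the peak, retaining contiguous bins
whose LOD stays within `si_drop` (default 1.5) of the peak, clamped at
chromosome ends; the interval spans the physical extent of the retained
bins.  Additive effects are (mean_B − mean_A)/2 — positive means the
parent-2 allele raises the trait — and variance explained is the R² of the
marginal single-marker regression at the peak (whether the original
analysis conditioned on the CIM covariates is unstated; the marginal model
is the simpler, reproducible choice).

One eQTL is kept per chromosome per e-trait (the chromosome-wise maximum).
The declared catalogues report 1–3 eQTLs per e-trait without a stated
multi-peak rule; chromosome-wise maxima reproduce that cardinality, and
secondary same-chromosome peaks are out of scope.

## Distribution statistics and hotspots

Counts against size-proportional expectations use expected_i =
total·size_i/Σsize, SR_i = (obs_i − exp_i)/√exp_i, χ² = Σ SR_i² with
df = k − 1 — the identity χ² ≡ Σ SR² is asserted on every result.  The
per-chromosome summary computes both the physical (Mb) and genetic (cM)
versions.  |SR| > 2.33 marks P < 0.01.

The hotspot screen assigns each trans-eQTL to its peak bin (not spread over
the SI, matching discrete per-bin counts) and requires two rejections at
α = 0.01: SR of the bin's trans count against its physical-size
expectation, and a hypergeometric upper tail with population = all
classified eQTLs, successes = all trans-eQTLs, draws = eQTLs peaking in the
bin — i.e., is the bin's eQTL content unexpectedly trans-heavy given its
cis content?  The hypergeometric construction is one reading of a
one-sentence description; alternatives (population = e-traits) would change
p-values and are not claimed equivalent.  Bins with SR < −cutoff are
coldspots.  Known behaviour: a strong hotspot bleeds into tightly linked
neighbour bins.  When the neighbouring bin sits within a few cM, a fraction
of target peaks land there by sampling noise, and once roughly eight
spillover trans-eQTLs accumulate, both tests fire for the neighbour as
well.  This is a property of single-bin counting at fine map resolution,
not of the implementation — real bin-map studies show the same adjacent
flagged bins — so exact-bin specificity should not be expected to exceed
~90% for a 150-target regulator at n ≈ 200; the validation study reports
the measured rate rather than hiding the neighbour flags.

## Co-expression, master regulators, iGA

Correlation significance is calibrated empirically: two disjoint random
groups of 1000 e-traits give 10⁶ cross-pair Pearson correlations, and the
α/2 tails become the positive and negative cuts (a skewed expression
distribution yields asymmetric cuts, e.g. +0.60/−0.52 at P < 0.01 in the
emulated study's scale).  Master-regulator nomination takes each cis-eQTL
gene and counts e-traits whose trans-eQTL *peak* falls inside its support
interval and whose correlation passes the cuts; N > 100 marks a master
regulator, 20–100 a secondary candidate.

For iGA over a functional gene set, group/member pairing uses *SI overlap*
(cis SI of the group vs trans SI of the member) — the two stages are
worded differently in the source protocol and each is followed literally.
Genes with both cis- and trans-eQTLs are disregarded in pairing.  Pairs
are pooled and ranked by |r| descending: ranking by absolute value rather
than signed r lets strong repression contribute, which matters because
validated repressive edges (negative correlations near −0.5) would
otherwise sink to the bottom of the list.  PC_j = P(X ≥ j) with
X ~ Hypergeometric(N_total, n_members, r_j); the PC value is the minimum
over prefixes, ties resolving to the smallest prefix within float
tolerance.  Groups with PC < 0.05 emit one signed edge per changed member
(sign = sign of r).  Term enrichment of target sets is a hypergeometric
upper tail per term with Benjamini–Hochberg adjustment across terms.

## pQTL integration

Phenotypes run through the same engine (default threshold 5.0).  Candidate
genes for a pQTL are cis-eQTL e-traits whose SI overlaps the pQTL SI by at
least one base pair (no minimum overlap is defined upstream), ranked by
the two-sided correlation test p-value t = r√(n−2)/√(1−r²); a per-pQTL
Benjamini–Hochberg flag at 0.05 is reported alongside the raw p-values.

## The simulator

RILs are modelled at fixation (F∞, fully homozygous) rather than by
explicit generation-by-generation selfing: the emulated bin map contains
no heterozygotes and the two-state chain is exact for the F∞ marginal.
The map function is Haldane (no interference, closed form).  Expression is
generated in topological order over the regulator DAG:
e_g = μ_g + a_g·x_g + Σ β·e_parent + ε with ε ~ N(0, σ²) on the log2 scale
(microarray convention after RMA-style preprocessing), μ_g ~ N(8, 1).
Coefficients are solved from variance fractions: a = σ·√(v/(1−v)) makes
the local variant explain v of the gene's variance (Var(x) = 1 for ±1
coding in a balanced RIL); regulator→target β is scaled the same way
against the regulator's marginal variance, with covariances between a
target's own locus and its regulator's locus ignored (anchors are placed
independently, so the approximation error is the LD between two random
bins).  Default fractions: ordinary cis effects 0.25 (the regime where the
bulk of real cis effects sit, ≥20% variance explained), regulators 0.5,
regulator→target 0.5, sign mix 70% activating.  Phenotypes are
Σ γ_b·x_b (+ λ·e_gene) + noise with effects rescaled to a target
heritability (default 0.5); traits may share causal bins (pleiotropy) or
be driven through a designated strong-cis gene's expression.

Per-line noise streams are keyed by the line *label*, which makes the
generator equivariant: permuting the line order of the genotype input
permutes the expression output identically — a property the tests assert.
Presence calls are all `P` by default; a configurable fraction of e-traits
receives random `A` calls to exercise the presence filter (kept if P/M in
at least ⌈n/3⌉ lines — 70 of 210).  The optional `coanchored_cis` knob
places extra cis genes in the first regulator's bin, emulating the fact
that a hotspot bin harbours several genes with local variants; this is
what creates competing candidate regulators for the iGA and colocalization
studies.

What the simulator does *not* emulate: crossover interference, segregation
distortion, epistasis, probe-level artefacts (cross-hybridizing probe
sets), batch effects, and non-Gaussian expression noise.  Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to microarray artefacts.

## Validation studies and sizes

The studies in `eqtlnet.studies` run on a desk-scale genome that keeps the
real map's totals (372.2 Mb, 1625 cM, 12 chromosomes) at 300 bins, chosen
so the full battery completes in minutes on one CPU:

* cis recovery / null calibration — 200 lines; 200 cis e-traits at 25%
  variance explained plus 200 null e-traits; threshold from 40 sampled
  e-traits × 150 permutations (6000 pooled maxima at α = 0.05).
* hotspot recovery — 20 replicates, 210 lines, one 150-target regulator
  among 320 e-traits, screen at α = 0.01.
* iGA recovery — 5 replicates, a 30-gene set containing the regulator, its
  10 targets (trans effects at 60% of target variance), 8 co-anchored
  decoys and unrelated cis genes.
* pQTL ranking — 20 replicates, a 65%-variance cis gene driving two traits
  (45% of trait variance each) against 22 interval-sharing decoys.

Typical results: ~96% cis detection with the true anchor inside the
reported SI, null false-positive rate within Monte-Carlo error of 5%, the
hotspot bin flagged in 100% of replicates (exactly one flag in ~90%, see
the spillover note above), the planted regulator's iGA group significant
with full target recall and correct edge signs, and the causal gene ranked
first for both traits in ≥90% of replicates.

## Numerical choices and degenerate inputs

Residual sums of squares below 10⁻¹² (relative) are clamped to avoid
infinite LODs on noiseless input; zero-variance genotypes and constant
traits yield LOD 0 rather than errors.  Quantiles use numpy's default
linear interpolation.  The SR cutoff is reported to two decimals (2.33 at
α = 0.01).  Correlation p-values clip |r| marginally below 1 to keep the
t transform finite on planted-identity inputs.  All randomness flows from
a single integer seed through named SeedSequence streams, so every output
is byte-reproducible.
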