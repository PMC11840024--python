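# Methods

## Scope and data flow

`pleiosweep` chains five analysis layers over harmonized GWAS summary
statistics: (1) ingestion/harmonization, (2) conditional and
conjunctional FDR, (3) genomic risk-locus definition and comparison,
(4) LD-score regression, (5) selective-sweep score enrichment. A
synthetic-data generator with planted truth supplies validated inputs
for all of them. Coordinates are 1-based inclusive everywhere; BED
output converts to 0-based half-open at the writer only.

## Harmonization (`sumstats`)

Inputs are headered delimited tables with a user column map. Validation
drops records with p outside (0, 1], non-finite z, non-positive n, or a
z inconsistent with beta/se beyond 1e-6 relative tolerance; `z = beta/se`
is derived when z is absent. `p = 0` is clipped to 1e-300 (the smallest
double comfortably representable in −log10 space) with a warning, not
dropped. Duplicate rsIDs keep the largest-n record. Traits are
intersected on rsID with positional agreement required; alleles align to
the first trait via identity, swap (z negated), strand flip, or flipped
swap; strand-ambiguous SNPs (A/T, C/G) are dropped by default because no
alignment is verifiable for them. The MHC
(chr6:25,119,106–33,854,733) is excluded by default before conditional
FDR estimation: its extreme LD would dominate the empirical conditional
cdf.

## Synthetic generator (`simulate`)

Two synthetic chromosomes (120 and 100 Mb) carry `m_snps` variants at
uniform random distinct positions, so cross-chromosome logic is always
exercised. LD is exchangeable within contiguous blocks: one correlation
`block_r` for every within-block pair, zero across blocks. Block
boundaries are drawn at uniformly random cut points (Dirichlet-uniform
sizes, coefficient of variation ≈ 1) — a crude stand-in for the wide
LD-block size spectrum of real genomes, and the variance in
`ℓ = 1 + (K−1)·block_r²` that makes the LD-score regression slope
identifiable. Equal-size blocks would make ℓ nearly constant and the
fit degenerate.

Effects are spike-and-slab: `round(m·pi_shared)` variants are causal in
both traits with bivariate-normal effects at correlation `rho_beta`
(constructed as `b2 = ρ·b1 + √(1−ρ²)·w`, exact at |ρ| = 1);
trait-specific causals are independent normals. Each trait's effect
vector is rescaled so the realized Σβ² equals the configured h² exactly
(a per-trait scalar, so `rho_beta` is untouched). z-scores follow the
LD model

    z = √n · (R β) + ε,    ε ~ N(0, R) blockwise,

with R the exchangeable block matrix; the same `block_r` spreads effects
and correlates noise (one fewer knob, declared simplification). Under
this construction `E[z_j²] = 1 + n·h²·ℓ_j/m` holds exactly, which is
both the generator's closed-form self-check and the reason LD-score
regression is unbiased on its output.

Defaults are the package's study conditions and are not tuned per
analysis: `m_snps = 20,000`, `n_blocks = 1,000`, `n = 50,000` per trait,
`h² = 0.3`, `pi1 = pi2 = 0.01`, `pi_shared = 0.005`, `rho_beta = 0.8`,
`block_r = 0.9`. `block_r = 0.9` was chosen so the exchangeable model
exercises the clumping conventions: with r² = 0.81 ≥ 0.6, same-block
SNPs are "dependent" at the independence threshold and collapse under
greedy selection; any `block_r² < 0.6` would make LD-aware thinning a
no-op. The power study configuration sets `pi1 = pi2 = pi_shared`
(pure-shared architecture) so that planted sharing is the only signal
and locus-level specificity is measurable against clean truth labels.

The truth table records per-SNP causal flags and, as "planted shared
regions", the positional extent of every LD block containing a shared
causal — the block is the generator's resolution of signal spread.

The sweep-score simulator lays i.i.d. standard-normal scores on the
panel positions, shifts means by δ inside planted sweep regions
(δ < 0 imitates the real track's signature of positive selection), and
masks a configurable fraction (default 0.6, reproducing the ~40 % join
coverage seen when candidate SNPs meet the public track).

What the generator does **not** emulate: realistic MAF spectra and
MAF-dependent power, genotyped-vs-imputed quality structure, full LD
matrices with decay (a block either correlates at `block_r` or not at
all), population stratification or sample overlap between cohorts, and
sex chromosomes. Passing tests therefore certify the estimators under a
clean polygenic model, not robustness to those real-data complications.

## Conditional/conjunctional FDR (`condfdr`)

The estimator is `condFDR(p1|p2) = p1 / F̂(p1 | P2 ≤ p2)` on a fixed
101×101 grid over −log10 p ∈ [0, 10] (p clipped below 1e-10 for binning
only; reported per-SNP p-values are untouched). Counts come from one
cumulative 2-D histogram; ties use "≤" throughout. No π₀ estimate is
applied, so values are conservative upper bounds. Three stabilizers:

- **Reliability floor**: cells whose joint-tail count is below 30
  inherit the nearest reliable cell toward looser p1 (the inherited
  value is never smaller, so the floor is conservative).
- **Monotonicity**: a cumulative minimum along the primary axis, so
  condFDR never increases as p1 becomes more significant.
- **Empty strata**: secondary columns with zero members inherit the
  nearest looser column.

Per-SNP values are bilinear interpolations of the grid in −log10 space,
clamped to the boundary beyond the last edge. The conjunctional FDR is
the elementwise maximum of the two directions; SNPs below 0.05 (the
conventional threshold) are flagged shared.

**LD-aware pruning.** With block labels available, the grid can be
averaged over random one-SNP-per-block prunings (default 100 iterations
when enabled). Unpruned estimation counts every SNP of an associated
block, overstating the conditional cdf where signal is LD-duplicated;
pruning removes that bias at the cost of grid resolution (pruned strata
hit the 30-count floor sooner). The pipeline leaves pruning off by
default for desk-scale exploration and the power study enables it.

A known, deliberate property: conjFDR controls the *SNP-level* error of
the flagged mixture. Under very strong enrichment a pure-noise SNP with
moderate p in both traits can clear the bound (its stratum is dominated
by true signal); such SNPs form singleton loci, so locus-level false
fractions run a few points above the SNP-level rate. The acceptance
power study measures exactly this and bounds it at 5 % plus Monte-Carlo
margin under the study conditions.

Stratified Q-Q curves report observed vs expected −log10 p1 with
expected quantiles −log10((i−0.5)/n) within strata p2 ≤ {1, 0.1, 0.01,
0.001}; upward drift with stricter strata is the enrichment signature.

## Locus definition (`loci`)

FUMA-convention constants, all configurable: significant = conjFDR <
0.05; independent significant SNPs by greedy thinning at r² < 0.6
(ascending conjFDR, ties by primary p then position); lead SNPs mutually
at r² < 0.1; candidate SNPs = conjFDR < 0.10 and r² ≥ 0.6 with an
independent significant SNP; loci span their candidates and merge below
250 kb. In the exchangeable model r² between two SNPs is `block_r²` if
they share a block, else 0, so every r² rule reduces to block
membership. Cross-analysis comparison counts interval overlaps and the
connected components of the union (the "distinct loci" number), and
reports lead SNPs common to both analyses. Novelty/specificity against
reference lists and positional gene mapping (gene interval ± window
intersects locus) are plain interval intersections.

## LD-score regression (`ldsc`)

Weighted least squares of z² (univariate) and z1·z2 (bivariate) on ℓ,
two-step: an unweighted pass supplies the heteroskedasticity weights
`1/(ℓ·2(1+n·h²ℓ/m)²)` (univariate) and
`1/(ℓ·((1+n₁h²₁ℓ/m)(1+n₂h²₂ℓ/m)+(√(n₁n₂)·ρg·ℓ/m)²))` (bivariate),
then one weighted refit. Inside a genetic-correlation fit the three
regressions share the bivariate weights, which makes `rg = 1` exact for
identical input traits. Standard errors are delete-one block jackknives
over 200 contiguous SNP blocks, computed from per-block normal-equation
sufficient statistics; rg jackknifes the full ratio. h² point estimates
are truncated to [0, 1] with the raw value retained; nonpositive h²
makes rg undefined with a reason rather than a number. No sample-overlap
correction (synthetic cohorts are independent by construction) and no
partitioned heritability.

## Sweep-score layer (`nss`)

The track is an input (chrom/pos/score TSV); the package never computes
sweep scores from alignments. Joins are exact on (chrom, pos) with
coverage logged (warning below 20 %). The enrichment Q-Q pairs candidate
against background quantiles at probabilities 0.01…0.99 with a one-sided
Mann–Whitney U (alternative: candidate scores smaller), suppressed below
10 scored candidates. The background is the scored panel (not the whole
track) so candidate and background share ascertainment; the whole-track
alternative is a caller choice. Multi-set comparison reports mean/sd/n,
BH-corrected pairwise two-sided Mann–Whitney tests, and the mean
ordering (the "in-between" statement). Gene scores are arithmetic means
over each gene's mapped, scored SNPs, ranked most-negative first.

The extreme-window scan uses 100 kb windows at 50 kb steps (defaults;
the published analysis's window scheme is not public, so these are
declared choices), skips windows with fewer than 5 scored positions, and
flags windows with mean ≤ the ceil(q·n)-th smallest eligible window
mean (q = 0.05). Ties at the threshold are all included — the flagged
fraction is exactly the tail plus tie mass — and flagged windows merge
into regions.

## Pipeline and reproducibility

One YAML-round-trippable config drives the run; every stage writes TSV/
BED with fixed float formatting, and the manifest records parameters,
stage status (absent inputs mark a stage "skipped", they never fail the
run), row counts and a sha256 per file — identical config and seed give
byte-identical outputs. With a third trait the two pairings are analyzed
separately and their locus sets compared (overlap, distinct union,
shared leads). All randomness flows from explicit seeds through
`numpy.random.default_rng`.

## Problem sizes used in validation

The test suite and acceptance script run at m = 20,000 SNPs /
1,000 blocks (null calibration: 100 seeds; power study: 20 seeds with
pruned grids; LDSC recovery: 50 seeds per ρ_β ∈ {−0.2, 0, 0.5}), with
smaller constructed instances for exact oracle comparisons. These sizes
give stable Monte-Carlo estimates for every property checked while
keeping a full run on one CPU in the tens of seconds; the estimators
themselves are vectorized and scale linearly in m.

## Known limitations

- The exchangeable-block LD model cannot represent partial LD between
  clumping thresholds (a pair is either above both r² cutoffs or below
  both at the default `block_r`), so the distinction between independent
  significant SNPs and lead SNPs only becomes visible for
  `0.1 ≤ block_r² < 0.6`.
- condFDR values are conservative bounds (no π₀), and locus-level false
  fractions exceed SNP-level rates under strong enrichment (see above).
- The jackknife SE treats contiguous SNP blocks as exchangeable; with
  very uneven block sizes the SE is approximate.
- Real-data harmonization handles biallelic SNPs only; indels and
  multi-allelic records are dropped as allele mismatches.
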