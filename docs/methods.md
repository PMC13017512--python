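# Methods

## Data model

A `GenotypePanel` holds a biallelic site table (1-based positions, strictly
increasing within a chromosome; a site is a transversion unless its alleles
are {A,G} or {C,T}), per-sample metadata (population, species, ploidy,
coordinates, age BP, coverage) and a sites × samples matrix of alt-allele
dosages with −1 for missing. Ploidy-1 columns hold pseudo-haploid calls in
{0, 1}; ploidy-2 columns hold diploid dosages in {0, 1, 2}. Dosage counts
the alt allele; polarity is irrelevant to every statistic in the package
(all are invariant under a consistent dosage flip d → ploidy − d) but is
fixed for determinism.

Pseudo-haploidization draws one read uniformly among reads carrying the ref
or alt allele at each site; reads carrying other bases are excluded before
sampling, matching biallelic-site semantics. Base- and mapping-quality
filtering is assumed to have happened upstream: the function consumes
pre-filtered base counts. Sites with zero eligible reads become missing.

EIGENSTRAT round-trips are byte-exact for files the package wrote. When an
`.ind` file carries no ploidy information, a sample is inferred diploid iff
it contains a dosage-2 call; an explicit `ploidies` argument or metadata
table overrides the inference.

## f-statistics

Per-site terms — (c−a)(c−b) for f3 with vertex c, (a−b)(c−d) for f4 — are
averaged over the complete-case site set of each statistic (sites with a
defined frequency in every population entering it). D is the ratio of the
f4-type numerator sum to Σ (p1+p2−2p1p2)(p3+p4−2p3p4). The F4-ratio is the
ratio of the two f4 block sums over the common complete-case set of all
five populations, jackknifed as a ratio; when the denominator f4 has
|Z| < 3 the result carries a `denominator_not_significant` warning, since
the ratio is then poorly identified.

Standard errors use the weighted delete-one-block jackknife (Busing, Meijer
& van der Leeden 1999) with block SNP counts as weights, so short terminal
blocks are down-weighted correctly. Blocks are contiguous: physical spans
(default 5 Mb, never crossing a chromosome) or runs of a fixed SNP count
(default 100 for ratios; count blocks do not restart at chromosome
boundaries, mirroring SNP-fraction-based blocking). Z = estimate/SE from
the full-data estimate. A statistic whose jackknife variance is exactly
zero (e.g. identically-zero per-site terms) reports Z = 0 with a
`degenerate` flag rather than an infinity.

The classic uncorrected outgroup-f3 is used: no within-population
heterozygosity correction is attempted, which is the natural convention for
single-sample pseudo-haploid populations (frequencies 0/1, the analogue of
treating pseudo-haploid genotypes as inbred). Consequence: with a
finite-sample vertex population the empirical f3 exceeds the population
value by E[c(1−c)]/n_chromosomes; the test suite accounts for this term
explicitly, and analyses should use a well-covered outgroup as vertex.

## qpAdm / qpWave

Both operate on X[i,j] = f4(left_i, left_last; right_j, right_last) with
the basis populations taken as the last-listed left and right populations
(the choice does not affect p-values or weights). With `allsnps` each cell
is computed on its own complete-case site set; otherwise all cells share
the intersection. The covariance of vec(X) is the delete-one-block
jackknife covariance (unweighted across blocks; count-mode blocks are
nearly equal-sized). Singular covariances are ridged with εI,
ε = 1e-9·trace/dim, and flagged.

The rank test finds the best rank-r approximation under the
covariance-weighted quadratic form by alternating generalised least squares
(each factor update is a GLS solve; initialisation from the SVD) and refers
the residual statistic to chi-squared with (rows−r)(cols−r) degrees of
freedom.

The mixture fit uses the bilinearity of f4: if the target's frequencies are
`Σ w_s · source_s` with `Σ w_s = 1`, the target's f4 row equals the same
combination of source rows against any right set unadmixed with the left
set. Weights solve this condition by iterated GLS — the residual covariance
depends on the weights through the contrast vector (1, −w), so the solve is
repeated to convergence. The residual statistic is referred to chi-squared
with n_right − n_sources − ... specifically (n_right − 1) − (n_sources − 1)
degrees of freedom, the standard qpAdm dof. This is a reimplementation of
the published qpAdm description validated here by simulation calibration
(clone targets fit with weight 1 and uniform-ish p; mixtures are recovered
to ±0.02 at 100k SNPs; targets with ancestry missing from the sources are
rejected or infeasible in essentially all replicates).

Weight standard errors re-solve the fit on each delete-one-block f4 matrix
(holding the covariance fixed) and apply the weighted jackknife to each
weight. Model selection: reject iff p < 0.01 or any weight is negative;
accepted models sort by p descending, ties broken by fewer sources, then
lexical source names. Period aggregation averages weights of accepted fits
per period; a period with no accepted model is absent from the output, not
zero.

## Co-ancestry

Spatial distances are haversine great circles on a 6,371 km sphere;
temporal distances are |Δ age| using midpoint ages (the mean of an interval
when only an interval is known). All similarity and distance matrices are
z-standardised over off-diagonal entries before modelling; a constant
matrix is a degenerate-input error.

MRM regresses the vectorised lower triangle of the response on the
predictors by OLS; per-coefficient significance permutes rows and columns
of the response jointly, p = (b+1)/(n+1) so p is never zero. Pairs with
|residual| > 4 SD are flagged (an exact fit, all residuals at floating-point
noise, flags nothing).

The partial Mantel statistic is the residual-correlation formulation: both
matrices are regressed on the covariate lower triangles, and r is the
Pearson correlation of the residuals. With no covariates this is exactly
the simple Mantel statistic. The permutation null jointly permutes rows and
columns of one side's residual matrix; the test is one-sided (greater),
matching the directional hypothesis of shared history, and the default
significance threshold is the conservative 0.0045 appropriate when both
matrices are spatially autocorrelated. Type-I error at nominal 0.05 is
calibrated to 5% ± 2% in the test suite (400 null draws, 999 permutations).

Paired outliers: per site pair, the difference (human − dog similarity) is
converted to a robust Z against the median and 1.4826·MAD (the normal-
consistent scale; the scale choice does not reorder |Z| flags), flagging
|Z| > 3.

## Kinship

P0 per 5 Mb window is the mismatch fraction over co-covered sites; windows
with fewer than 10 co-covered sites are dropped so near-empty windows
cannot dominate the jackknife. Diploid samples are pseudo-haploidized on
the fly (one random allele per site, seeded) so all comparisons are
haploid–haploid. The per-pair mean P0 over windows is normalized by the
median over all pairs (requiring at least 3 pairs) and reported as
theta = 1 − P0/median, so the median pair has theta = 0 by construction.
This is a relative scale — the mapping onto absolute kinship coefficients
and degree cutoffs is a convention left configurable — which suffices for
ranking pairs and detecting close relatives against an unrelated
background. SEs come from a delete-one-window jackknife in which the median
is recomputed per deletion.

## Synthetic data generator

Root allele frequencies are uniform on [0.05, 0.95]; each edge applies
Balding–Nichols drift (child ~ Beta with mean p and variance F·p(1−p)),
chosen over truncated-normal diffusion for its closed-form moments; an
admixture event sets a node to a fixed linear mixture of two parents.
Because E[child | parent] = parent and E[child² | parent] =
(1−F)p² + Fp, all first and second cross-moments of node frequencies
propagate in closed form down the graph; `expected_f2/f3/f4` evaluate any
f-statistic exactly and serve as the independent oracle throughout the
tests. Genotypes are binomial in the population frequency; per-sample
coverage is Poisson(mean_depth) with zero depth giving a missing call, so
the missing rate is exp(−mean_depth).

Preset design. Edge drifts (0.005–0.15) are package constants producing
f-statistic magnitudes typical of canid panels. The wolf-admixture preset
places the admixing wolf parent on the sampled wolf's own lineage and the
dog parent adjacent to the western reference's ancestor, so the F4-ratio
with the standard roles is exactly (1 − wolf fraction) in expectation —
verified against the moment oracle. The Mesolithic preset mixes at the
western/eastern ancestor nodes with sources branching directly off them,
so the two-source qpAdm model holds exactly; rights are three wolves, two
eastern dog offshoots (dingo and American-dog roles, the informative
rights) and the coyote outgroup. Ancient populations are sampled as three
pseudo-haploid individuals at 5× mean depth, modern reference populations
as two diploids at 20×; these sizes give desk-scale Monte-Carlo precision
(per-seed F4-ratio SE ≈ 0.03 at 100k SNPs) while staying in the regime of
real ancient panels. Sites are laid out across 20 chromosomes at 10 kb
spacing so both physical-span and SNP-count blocking behave sensibly.

Coupled histories: site coordinates uniform in a Europe-sized box
(lat 35–60, lon −10–40), ages uniform over 1,500–16,000 BP. Human and dog
similarity matrices are linear mixtures of a shared standardized latent
Gram matrix S (rank 5), the negated standardized distance matrices, and
independent symmetric noise, with coefficients √|ρ| on S and √(1−|ρ|) on
the noise; since the components are independent with unit off-diagonal
variance, the population partial correlation given space and time is
exactly ρ (recovered empirically to ±0.01 over 50 seeds). Outputs are
z-standardised, matching the analysis convention.

Related pairs: one individual's calls are copied into another at a random
site fraction equal to the requested theta; copied sites never mismatch, so
the expected median-normalized theta equals the copy fraction.

What the generator does not emulate: linkage disequilibrium within blocks
(sites are exchangeable, so physical blocks are conservative stand-ins for
LD blocks), post-mortem damage and reference bias, non-uniform SNP
ascertainment, and population-size dynamics beyond per-edge drift
magnitudes. Passing tests therefore demonstrate estimator correctness and
calibration under the generative model, not robustness to those real-data
artefacts.

## Randomness and reproducibility

Every stochastic entry point takes an explicit seed and builds its own
`numpy` Generator rather than sharing package-level state; fixed seeds
reproduce panels bit-for-bit, and CLI outputs carry a provenance header
(package version, seed, config hash). Simulation sizes used by the test
suite and the acceptance script (100k SNPs, 20–50 seeds, 999 permutations,
400 calibration draws) were chosen to keep full runs within a few minutes
on one CPU while leaving Monte-Carlo error well inside the stated
tolerances.

## Known limitations

- The uncorrected outgroup-f3 is biased upward by finite vertex sample
  size; use a well-covered outgroup, or many vertex samples.
- qpAdm p-values rely on the chi-squared reference for the GLS residual;
  with very few jackknife blocks the covariance estimate is noisy and the
  ridge kicks in (flagged).
- The partial Mantel permutes residual entries (the classic approximation)
  rather than re-residualizing raw matrices per permutation.
- theta is relative to the panel's median pair: panels dominated by
  relatives violate the unrelated-median assumption.
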