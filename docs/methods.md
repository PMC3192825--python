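# Methods

`linksel` studies how natural selection at genic sites shapes *linked,
putatively neutral* variation: the correlations of window-level diversity
and allele frequency with recombination rate and genic content, and the
population-genetic models (background selection, selective sweeps, or
mixtures) that can produce them.  This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data-driven test suite does and does not establish.

## Low-coverage allele-frequency model (`lowcov_maf`)

Reads at a site are modeled per individual: genotype `g ∈ {0,1,2}` copies
of the minor allele under Hardy-Weinberg at frequency `q`, and each read
miscalled with probability `e` uniformly to one of the other three bases.
The per-read probability of showing the minor base is

    p_0 = e/3,    p_1 = 1/2 − e/3,    p_2 = 1 − e.

Two estimators:

* **Method of moments.**  The minor-base read fraction `f` (second-most
  common base, ties broken A<C<G<T and flagged) has expectation
  `q(1−e) + (1−q)e/3`; inverting gives `q̂ = (f − e/3)/(1 − 4e/3)`,
  clamped to `[0, 0.5]`.  This is the unique unbiased linear inversion
  under the uniform-miscall model and reduces to `f` at `e = 0`.
* **Maximum likelihood.**  `L(q) = Π_i Σ_g Binom(k_i | n_i, p_g) HWE(g|q)`
  over individuals, maximized on `q ∈ [0,1]` by a 512-point grid scan
  followed by bounded scalar refinement to `1e−6` (the grid guards
  against the bimodality that folding can induce), then folded to MAF.

Sites are downsampled to a 100-read cap (uniform without replacement
across reads, via a multivariate hypergeometric draw over
individual×base cells) so coverage is comparable genome-wide; sites under
the cap are skipped.  The two-stage pipeline evaluates ML only where the
MoM estimate exceeds 1%, and calls SNPs where the ML estimate strictly
exceeds 5%.

Numerical notes: `0·log 0` terms are handled by `xlogy`, making `e = 0`
and boundary `q` exact.  At `q = 0.5` *any* folded estimator is biased
downward (`E[min(q̂, 1−q̂)] < 0.5` whenever `q̂` has spread); bias at the
fold point is therefore assessed on the unfolded estimate
(`ml_maf(..., fold=False)`) against the planted minor allele — only
possible in simulation, which is where the assessment lives.  At ~0.05×
per-individual coverage nearly every individual carries at most one read,
where ML and MoM coincide analytically; the RMSE comparison between them
is run as a paired per-site contrast with a 2-SEM Monte-Carlo allowance.

## Window summaries (`window_summaries`)

Non-overlapping 100 kb windows; windows overlapping a 10 Mb exclusion
zone around centromeres, telomeres, or chromosome ends are dropped, and
trailing partial tiles are discarded.  Variants are filtered to biallelic
reference-matching SNPs outside repeat and conserved-element masks, at
least 2 bp from declared indels/SVs ("within 2 bp" is read as distance
< 2 removed, ≥ 2 retained; configurable), and inside the coverage mask.

The divergence-normalized diversity is `S_norm = (S/covered)/(d/aligned)`.
The raw-count denominator `(S/covered)/d` is available by flag because
the reference description is ambiguous about whether the difference count
was normalized by aligned bases; the ratio form is the default since it
is scale-free when SNP coverage and alignment coverage differ.  Windows
with `covered = 0` or `d = 0` are flagged invalid and excluded from
correlation inputs.  Genic windows have ≥ 50% transcript overlap,
non-genic windows have zero overlap, and windows in between belong to
neither class.  A heterozygosity outlier rule for 6-diploid genotype data
drops windows with ≥ 10 SNPs whose mean heterozygote count exceeds 3 of
6 (collapsed-duplication suspects).  Tajima's D uses the standard
`a1…e2` constants and is undefined for `S = 0` or `n < 3`.

## Coding divergence (`codon_divergence`)

Nei-Gojobori site counting from the human sequence only: each eligible
codon position contributes the fraction of its three possible single-base
changes that are synonymous to `L_S` and the complement to `L_N`
(`L_N + L_S = 3 ×` eligible codons exactly).  Observed human-chimp
differences are classified per site holding the other two codon positions
at the human alleles — matching a per-site annotation pipeline rather
than Nei-Gojobori pathway averaging over multi-hit codons.  Changes to or
from stop codons count as nonsynonymous; codons containing an internal
stop are skipped with a warning; ambiguous bases are skipped.
Minus-strand models are complemented in transcription order.  Conserved
element masks are deliberately *not* applied to coding divergence, and no
multiple-hit correction is made: `d_N = D_N/L_N` is a raw proportion.

## Correlation machinery (`correlation_suite`)

Spearman with average-rank ties; partial Spearman from the precision
matrix Ω of the rank correlation matrix, `ρ_xy·z = −Ω_xy/√(Ω_xx Ω_yy)`
(equivalent to the R `pcor` recipe), with complete-case analysis and an
error naming collinear controls when the matrix is ill-conditioned
(condition number > 1e12).  The genic/non-genic contrast permutes group
labels with sizes fixed; p-values use the add-one convention
`(#{Δρ_perm ≥ Δρ_obs}+1)/(n+1)` so they are never zero, with the raw
proportion also reported.  The test is one-sided (genic > non-genic),
matching the directional claim it serves.  Bootstrap CIs are percentile
intervals over window resamples; degenerate resamples are redrawn and
logged.  Display binning sorts by the key (ties broken by genomic
coordinate), averages consecutive groups of 50 windows, and flags a
trailing partial bin.  No multiple-testing correction is applied.

## Synthetic data (`synthetic_data`)

All pipeline inputs can be generated with known ground truth: pileups
(above), BED-style masks (independent 500-bp blocks, so realized masked
fractions are binomial around the request), window feature tables from a
Gaussian copula (chosen because its rank correlation has the closed form
`(6/π)·asin(ρ/2)`, giving the generator an exact self-check), and paired
human/chimp CDS with exact planted synonymous/nonsynonymous difference
counts (one substitution per codon, stop codons excluded from both
sequences).  Default marginals are framed on human-like values:
recombination lognormal with median ≈ 1.1 cM/Mb, GC ≈ 0.41, divergence
≈ 1.2% of a window, ~35% of bases covered.  What these fixtures do *not*
emulate: mapping artifacts, base-quality miscalibration, indels and
structural variation, CpG hypermutability, and spatial autocorrelation of
features along a chromosome — tests passing on them show the estimators
and accounting are correct, not that real data are free of those effects.

## Forward simulator (`wf_simulator`)

Discrete-generation Wright-Fisher with viability selection
(multiplicative across sites; within a locus fitness `1, 1+hs, 1+s` with
`h = 0.5`), an infinite-sites Jukes-Cantor mutation model at
`μ = 2.5e−8` per bp per generation, and crossovers placed by
inverse-CDF sampling from the window's hotspot map (Poisson crossover
counts with mean equal to the rescaled map length).

* **Window layout.**  8 exons (1.5 kb) and 7 introns (5 kb) split as
  4 exons + 3.5 introns on each side of a central 53 kb neutral
  intergenic block — 100 kb in total.  Exon and intron sizes are not
  published for the reference design (only the counts and the 53 kb
  block); the defaults make the arithmetic close at 100 kb and are fully
  configurable.  Codon positions 1-2 of exonic bases are nonsynonymous
  targets, position 3 synonymous (frame runs left to right across
  exons).  Reduced runs may scale all features (`scale`) or only the
  intergenic observation block (`intergenic_scale`), the latter
  preserving the full selected architecture.
* **Hotspots.**  2 kb hotspots with Exp(20 kb) inter-hotspot gaps laid
  left to right (a hotspot that would overrun the window is discarded);
  hotspot intensities are `0.8·x_i`, `x ~ Dirichlet(1,…,1)` over the k
  hotspots (the symmetric reading of the published scheme), background
  segments share 0.2 via an independent Dirichlet.  If no hotspot fits,
  all mass is background.
* **Demography.**  Ancestral 20,000 diploids; split 200,000 generations
  ago (5 Myr at 25 yr/gen) with 2-fold contractions to 10,000 on each
  branch; optional human bottleneck to 1,000 diploids between 1,500 and
  1,000 generations before present.  The bottleneck block stands in for
  published European fits whose parameters are not reproduced here; it is
  configurable and disabled with `bottleneck=False`.
* **Selection models.**  Negative windows draw nonsynonymous effects
  from a gamma DFE (shape 0.184, mean |s| = 0.03 — external-source
  defaults, configurable) and make a fraction of intronic mutations
  weakly deleterious (defaults 50% at s = 7.5e−5); positive windows make
  0.5% of nonsynonymous mutations beneficial at s = 0.625e−2 with the
  rest neutral; mixtures assign window types with probabilities p⁺/p⁻
  independently of recombination rate.  Biased gene conversion is not
  modeled (its source parameterization is not published); the design
  leaves room for a transmission-bias hook.
* **Rescaling.**  A factor λ divides population sizes and times and
  multiplies μ, r and s, preserving 4Nμ, 4Nr and 2Ns.  λ = 40
  reproduces the reference configuration (ancestral size 500).  Strong
  positive effects saturate fixation probabilities as λs approaches 1,
  so sweep-bearing runs here keep λ ≤ 125.
* **Initialization and burn-in.**  `init="monomorphic"` runs a 10·2N
  generation burn-in from zero variation.  `init="coalescent"` (default)
  plants neutral-class variation from an msprime stationary coalescent
  (uniform recombination at the map average) and runs a 2·2N forward
  burn-in during which selected classes fill toward mutation-selection
  balance; this trades a small transient for a ~5× speedup and
  calibrates within ~5% on diversity and divergence closed forms.
* **Bookkeeping.**  Every mutation is accounted for exactly:
  generated = fixed + lost + segregating per lineage, with ancestral
  segregating sites handed to both branches at the split.  Fixations are
  detected at column-compaction steps (every 4 generations by default),
  so fixation times carry a ≤ 4·λ-generation quantization.
* **Measurement.**  Mirrors the data pipeline: intergenic-only
  summaries; optional analyzed-length draws from an empirical coverage
  distribution; SNPs from population MAF > 5% (low-coverage analogue) or
  from a 6-diploid sample (genotype analogue, with π and Tajima's D);
  divergence compares one human with one chimp individual, counting
  opposite homozygotes as 1 and any heterozygote as 0.5; simulated `d_N`
  is the per-site fraction of differences at codon positions 1-2.

## Problem sizes used by the test suite

The suite must run on one CPU in well under half an hour, so the
simulation studies are desk-scale reductions of the reference conditions
(which call for 20,000 windows, or 1,000 replicates per model at ~30-60
min each):

* Neutral calibration: 240 stationary 10 kb windows at λ = 100
  (N = 100), 1,200 generations, 10 cM/Mb; ~10,500 pooled sample SNPs for
  the SFS check.  Because sites within a window share genealogies, the
  SFS shape is tested per frequency bin against replicate-scatter
  standard errors rather than a multinomial χ².
* Model contrasts: 25 kb windows; neutral and background-selection
  models n = 100 at λ = 160, sweep-only n = 150 at λ = 100, mixture
  n = 60 at λ = 160; rates binned from the generator's lognormal pool.
* Sweep-fixation fraction: 32 sweep-capable full-architecture 100 kb
  windows at λ = 80, scaled by the 5% mixture weight.
* Estimator suite: 130 sites per true frequency in
  {0.1, 0.2, 0.3, 0.5}, 2,000 individuals, 100-read cap, e = 1%.

At these sizes the background-selection-versus-neutral *ordering* of
ρ(S_norm, recombination) and the mixture model's d_N correlation interval
are underpowered relative to their reference-scale formulations, and the
corresponding checks can fail even though the underlying effects are
directly demonstrated elsewhere in the suite (equilibrium diversity under
background selection drops to ~0.77·θ at 0.1 cM/Mb and returns to θ at
5 cM/Mb; recent sweeps reduce within-window S with rank correlation
≈ −0.44).  The sweep-fixation fraction measures ~4-5% of windows with a
recent beneficial fixation under the default layout versus a reported
2.3%; the quantity is directly proportional to the nonsynonymous target
length, which the reference design does not publish, so the default
8 kb target plausibly overstates it — the measured value and its
binomial CI are reported as-is.

## Known limitations

* Windows are simulated independently; selection outside a window that
  would be linked to it in a real chromosome is absent, understating
  linked-selection effects for a given per-site selection density.
* The coalescent initializer plants no selected standing variation;
  results within ~2N generations of initialization underrepresent
  deleterious segregation (the branch phases are long enough that final
  summaries are unaffected at the tested tolerances).
* Fitness factors are clamped below at 1e−12, so at large λ strongly
  deleterious gamma draws become effectively lethal rather than
  proportionally selected; their background-selection contribution is
  already negligible at the tested λ.
* The divergence comparison ignores multiple hits (raw proportions), as
  does the Jukes-Cantor mutation scheme at these divergence levels.
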