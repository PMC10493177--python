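# Methods

## Genotype model

A synthetic haplotype for ancestry group *s* tiles each chromosome with
segments drawn sequentially from the chromosome's start in genetic-map
coordinates. Per segment:

1. a donor ancestry group is drawn (fixed label, or i.i.d. from the
   configured admixture proportions),
2. a donor haplotype is drawn uniformly among that group's haplotypes,
3. a coalescence age `T ~ Gamma(shape 2, rate Ns/Ne)` is drawn, where `Ns`
   is the number of reference haplotypes in the donor group (2× its
   individuals) and `Ne` the group's effective population size,
4. a segment length `ℓ ~ Exp(rate 2·T·ρ)` in cM is drawn; the final segment
   is truncated at the chromosome end.

The Gamma law is parameterized by *rate* `Ns/Ne` (mean `2·Ne/Ns`): a larger
reference panel implies a genealogically closer nearest donor, hence a
smaller T and longer faithfully copied segments, which is the
demographically sensible direction. This scale-versus-rate choice is a
genuine modelling decision (the distribution could be read either way) and
is centralized in `sample_coalescence_age`.

Within a segment the donor's alleles are copied imperfectly: the alternate
allele at variant *i* survives only if `T ≤ m_i` (mutation age), otherwise
the site reverts to the reference allele. Missing ages are `+inf`, so the
filter is strictly opt-in per variant; a single `age_scale` scalar at load
time puts externally published ages on the same time scale as T, since that
linkage is not derivable from either side alone. Suppression is monotone:
lowering any `m_i` can only remove alternate alleles, never create them.

Variants are assigned to segments by half-open cM intervals
(`[start, end)`, boundary variants belong to the right segment); bp→cM
conversion is piecewise-linear between map knots with constant extrapolation
beyond the terminal knots. Two independent haplotypes per individual are
summed into dosages in {0, 1, 2}. The two haplotypes share no state; whether
a generator of this kind should redraw T per segment or per haplotype is
ambiguous — per-segment redraw is used, matching the sequential reading of
the model.

**Admixture caveat:** drawing the donor group i.i.d. per segment produces
genotypes whose marginal ancestry proportions are correct but whose
segment-length distribution does not reflect any real admixture history;
interpret admixed output with care.

**Reproducibility contract:** every (sample, haplotype) pair draws from an
independent substream, `SeedSequence(seed, spawn_key=(sample, hap))`, and
segment draws are consumed in fixed-size blocks of 64, so output is a pure
function of (inputs, seed) — bit-identical across batch sizes and worker
counts. `batch_size` and `--threads` can only affect speed.

PLINK1 output is written variant-major after the full dosage matrix is
assembled in memory; this is an explicit simplicity choice at the cohort
sizes this package targets (10³–10⁴ samples), not an I/O constraint of the
model.

## Phenotype model

Traits are sums of three components computed on N samples:

* genetic: `G @ β` on raw allele counts (not standardized genotypes — the
  weighted sum of causal allele counts),
* covariate: optional user matrix times weights,
* environmental: standard normal draws.

Each component is rescaled by its empirical standard deviation so the
realized variance shares equal `h2`, `covariate_fraction`, and the
remainder exactly per run (up to the sampling correlation between
components, O(1/√N)). This empirical calibration is chosen over analytic
scaling because it holds under arbitrary LD between causal variants.

Causal SNPs are a uniform draw of `round(polygenicity × #polymorphic)`
(minimum 1) among polymorphic SNPs. Effects are zero-mean normals with
variance `[p(1−p)]^a · r^b · s^c` times a mixture component's relative
variance; `r` is an LD score, defined here as 1 + Σ r² over neighbours
within a 1 cM window (the "local linkage structure" factor is not a
standardized quantity across tools, so the definition is documented rather
than assumed universal). Defaults `a = −0.25, b = −0.25, c = 0` with
`s ≡ 1` are placeholders in the spirit of empirically observed MAF- and
LD-dependent architectures; they are configuration, not estimates, and any
study should set them deliberately.

Binary traits code the top `prevalence` fraction of the liability as cases
(2) and the rest as controls (1), ties broken by sample order. The quantile
rule gives the configured prevalence exactly, at the cost of not being a
Gaussian-threshold liability model.

Multi-trait ("shared-causals") and cross-ancestry effects reuse one causal
set with per-trait/per-population effects drawn from a multivariate normal
with the configured correlation matrix (PSD enforced; rank-deficient
matrices such as all-ones are handled by an eigenvalue square root, so a
correlation of exactly 1 with equal marginals yields identical effect
vectors). "independent-causals" draws disjoint sets per trait, making
cross-trait effect correlation approximately zero. β always refers to the
panel's alt allele.

## Evaluation metrics

* **MAF divergence**: mean absolute per-SNP MAF difference. Deliberately
  simple; other tools may report other divergences, so cross-tool numbers
  are not comparable.
* **LD decay**: mean r² (squared Pearson correlation of dosages) per
  pairwise-distance bin, default 50 bins over [0, 1] cM (Mb without a map,
  recorded as a warning); SNPs with MAF < 0.001 excluded; empty bins are
  missing, not zero. Curve distance is Euclidean over mutually populated
  bins.
* **PC alignment**: PCA is run separately on each dataset's standardized
  dosages; the score is the mean over the first 20 PCs of the absolute
  cosine similarity between corresponding variant-loading vectors (absolute
  value absorbs eigenvector sign indeterminacy; loading space is used
  because the two datasets share variants, not samples; the mean gives one
  scalar per comparison).
* **Adversarial accuracy**: 1-nearest-neighbour discriminator with mean
  absolute dosage distance, self excluded within set; 0.5 = chance,
  0 = copies. The distance is fixed (not configurable) because neighbour
  ranking under other metrics differs on {0,1,2} data.
* **Kinship**: KING-robust between-family estimator with standard degree
  thresholds 2^−1.5 / 2^−2.5 / 2^−3.5. "Closely related" for the two
  percentages below means duplicate/MZ or first degree.
* **Generalizability** `(1 − Ncross/(Nsyn·Nref))×100` and **diversity**
  `(1 − Npairs/(Nsyn²−Nsyn))×100`. The diversity denominator counts ordered
  pairs, so unordered within-cohort counts are doubled first; this keeps
  the printed denominator exact.

All metrics are deterministic (no internal RNG).

## ABC parameter selection

Per ancestry group, `n_train` (ρ, Ne) points are drawn uniformly from the
prior box, a reduced cohort (default 200 samples) is simulated at each, and
summaries are computed: the LD-decay vector (default 25 bins over [0, 1]
cM) and the per-sample (duplicate, first-degree, second-degree)
cross-relatedness counts against the reference. A Gaussian-process emulator
(RBF + white noise, one GP per summary dimension, inputs scaled to the
prior box, outputs standardized; constant outputs short-circuit to the
constant) maps parameters to summaries; its contract is that training-point
predictions beat the constant-mean predictor in MSE. Rejection sampling
draws `n_draws` parameters from the prior, predicts summaries, and accepts
the `accept_quantile` fraction closest to the observed target — the panel's
own LD decay plus a zero relatedness vector. The LD objective uses
Euclidean distance on the LD block; the multiobjective sums the LD and
relatedness distances after dividing each by its pool standard deviation
(equal weights; a zero-variance block drops out). Selected parameters are
the posterior means.

The two objectives trade off: LD-optimal parameters copy longer segments
and sit closer to the reference (more cross-relatives); the multiobjective
shortens segments, trading some LD fidelity for generalizability. The test
suite checks this direction holds on the fixture panel.

## Fixture panels

Test panels use a founder-pool construction: `n_blocks` contiguous blocks,
each with a pool of `within_block_pool` founder haplotypes (site frequencies
Beta(0.8, 0.8)); each haplotype picks a founder per block and flips sites
with probability `mutation_noise` (default 0.01). This gives strong
within-block LD, ~zero between-block LD, separable ancestry groups
(independent pools), a uniform 1 cM/Mb map, and i.i.d. exponential mutation
ages (mean 20, several times the default E[T] ≈ 5, so the age filter trims
the youngest variants rather than gutting the panel). Defaults: 200
haplotypes × 2000 SNPs at 10 kb spacing (≈ 20 cM), generated in well under
a second.

What the fixtures do **not** emulate: recombination-rate variation, allele
frequency spectra of real populations, demographic history, admixture LD,
or rare variants. Passing tests therefore demonstrate correctness of the
machinery and its calibration contracts, not population-genetic realism of
the output on real panels.

## Problem sizes and numerical choices

Test and calibration runs use desk-scale sizes chosen as the smallest at
which the measured quantities stabilize: 5000 samples for heritability
calibration (±0.02), 500 + 500 samples for the adversarial-accuracy
baseline (±0.05), 10⁴ draws for effect-correlation checks, 10⁶ draws for
the segment-law moment checks (±1%), and ~200-sample training cohorts for
ABC. Tolerances on Monte-Carlo assertions are set to ≥ 3 standard errors of
the estimator at those sizes. Degenerate inputs fail loudly: unphased or
multiallelic panel records, dosages outside {0,1,2}, zero-variance genetic
components with h² > 0, kinship on heterozygote-free pairs, maps with
fewer than two knots.

## Known limitations

* No de novo mutations; variation is bounded by the reference panel.
* No explicit coalescent/demographic simulation; T is a per-segment scalar,
  not a genealogy.
* Phenotypes have no gene–environment interaction, dominance, epistasis, or
  sex chromosomes.
* No differential-privacy accounting: low relatedness and AA ≈ 0.5 are
  necessary, not sufficient, for privacy. Use public reference panels only.
* The PLINK writer keeps the cohort dosage matrix in memory (variant-major
  layout); very large cohorts would need a transposed spill-to-disk path.
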