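# Methods

## Estimator

At SNP loci where the mother is homozygous, the percentage *X* of sequenced
plasma bases that differ from the maternal allele decomposes into a fetal
signal and an error baseline. If a fraction π of panel loci is
fetal-informative (mother homozygous, fetus heterozygous for the other
allele), a plasma sample with true fetal fraction *f* (percent) contributes
fetal-specific bases at rate π·f/200 per panel base, and
sequencing/genotyping errors add a constant ε/100 per base. Hence

    E[X] = π·f/2 + ε          (percent scale)

which inverts to the linear calibration F̂ = a·X + b with a = 2/π and
b = −a·ε. The calibration is fitted by unweighted ordinary least squares of
the gold-standard fraction on X; nothing in the error model suggests a
weighting scheme, and the residual variance is dominated by counting noise
that is roughly homoscedastic over the observed X range at a fixed depth.

The gold-standard fraction itself is computed from loci where the fetal
genotype is known to be heterozygous: F = 2p/(p+q)·100, with p the bases
carrying the fetal-specific allele and q the bases carrying the shared
maternal allele; bases matching neither locus allele are ignored.

## Allele counting

- Coordinates are 1-based, fully closed (VCF convention); BED export is
  0-based half-open. Chromosome names are compared after stripping a
  leading `chr` prefix.
- Multi-allelic records and indels are excluded outright: the error model
  assumes biallelic SNVs, and decomposition would entangle error rates.
- Sex chromosomes are excluded from the panel by default (an
  `include_sex` flag restores them): for a male fetus, chrY-mapping reads
  are wholly non-maternal and would break the linear relationship.
- Default filters: base quality ≥ 20, mapping quality ≥ 20; duplicate,
  secondary, supplementary and unmapped records excluded. The thresholds
  are configurable; the defaults suppress error inflation while keeping
  the constant-error assumption plausible.
- Any A/C/G/T base differing from the maternal allele counts as
  non-maternal — not only the panel's known alternative allele — since the
  calibration's intercept absorbs the error baseline wherever it lands.
- One base per template per locus: when overlapping mates of a pair both
  cover a site, only the higher-quality base is counted. Deletions,
  reference skips and N bases over a site are tallied as discarded.

## Evaluation machinery

- **Deviation spread.** "95% confidence interval" of the deviations
  F̂ − F means the empirical 2.5th/97.5th percentiles with linear
  interpolation between order statistics — a distribution-free summary
  with no normality assumption. It needs a few dozen points; below 20 a
  warning is raised.
- **Cross-validation.** Fold assignment is a seeded shuffle followed by
  contiguous chunking; when k does not divide n the first n mod k folds
  take one extra sample. The per-fold score is the prediction R² on the
  held-out fold (1 − SS_res/SS_tot), undefined (NaN) for singleton folds.
  Held-out deviations are pooled across folds for the overall spread.
- **Read downsampling** works at the template level when per-read data
  exists; on aggregate counts it is binomial thinning with keep
  probability n_target/n_available, statistically equivalent for
  independently sampled bases.
- **SNP downsampling** is a uniform without-replacement subset on panels
  and site-level data. On aggregate counts (no per-locus identity) it is
  binomial thinning by n_snps/n_loci; this ignores the hypergeometric
  variance of the informative-locus share in the subset, which is
  O(π(1−π)/n_snps) — about 0.5% relative at 300K loci, far below counting
  noise at the depths where the grid operates.
- **Accuracy grid.** For each (read-pairs, SNP-count) cell, every sample
  is independently downsampled on both axes in each of `reps` replicates
  (default 20); deviations are pooled across replicates and samples before
  taking percentiles, maximising the sample size behind the percentile
  estimate. A cell whose target exceeds what any sample has is marked
  missing and the run continues.

## Synthetic data generator

The generator emulates a clearance-study population: maternal plasma
sampled before delivery (high fetal fraction) and serially afterwards
(fraction decaying to ~0), measured over a maternal-homozygous panel.

Defaults, set once:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 1,940,000 | homozygous loci retained from a 2.35M-SNP array |
| `pi_informative` | 0.10582 | probability a panel locus is fetal-informative |
| `epsilon_pct` | 0.34921 | baseline non-maternal error, % of bases |
| `coverage` | 4.5 | fold-coverage; ~139.5M pairs of 2×50 bp over 3.1 Gb |
| `f_true_pct` | 10.0 | true fetal fraction, % |

π and ε are back-derived from the published calibration (a = 2/π = 18.9,
b = −a·ε = −6.6): they make the simulated population reproduce that line
exactly in expectation, so the published accuracy figures become the
natural reference surface for the pipeline. They are algebraic
constructions, not measured quantities. Coverage converts to read pairs
via a 3.1 Gb genome at 100 bp per pair, so 1M pairs ≈ 0.032×.

The cohort preset `clearance_study` draws ⌈n/6⌉ samples with
f ~ Uniform(8, 30)% and the rest with f ~ Uniform(0, 3)%, mimicking the
pre/post-delivery mix; per-sample RNG streams are spawned deterministically
from the cohort seed, so a fixed seed fixes every count.

Modes:

- `aggregate` — genome-wide scalar counts: total bases N ~ Poisson(n_loci ×
  coverage), non-maternal bases ~ Binomial(N, π·f/200 + ε/100), informative
  bases ~ Binomial(N, π), fetal-specific bases ~ Binomial(informative,
  f/200). Fast at any panel size; used for the study-scale evaluations.
- `site_level` — per-locus depths Poisson(coverage), informative status
  Bernoulli(π), fetal and error bases drawn per locus and attributed to
  concrete alleles; flows through the same pileup-summary code paths as
  real data. In this mode errors are drawn from the bases left after the
  fetal draw, making the non-maternal rate smaller than the aggregate
  formula by the cross term f/200 × ε/100 (~2·10⁻⁵ at f = 10) — far below
  counting noise.
- `sam_emit` — writes a SAM plus maternal/fetal VCFs realising a
  site-level draw, for end-to-end I/O tests. Reads are unpaired 50 bp
  segments, one panel locus each (loci spaced 200 bp); mate-overlap and
  duplicate handling are exercised by dedicated hand-written SAM fixtures
  instead.

What the generator does **not** model: real read sequences, fragment-size
differences between fetal and maternal DNA, GC bias, copy-number variants,
locus-specific error rates, or genotyping error in the maternal array calls
beyond the constant ε. Passing tests therefore show
that the pipeline is correct under the estimator's own assumptions, not
that those assumptions hold on any particular sequencing platform — the
calibration must be refitted per platform.

## Numerical choices

- Negative predictions (X below the line's root) are returned as-is with a
  warning rather than clipped, so behaviour near F ≈ 0 stays analysable;
  `clip_zero` floors them for end-user reports.
- Model JSON round-trips floats at full precision.
- Downsampling targets equal to the available amount are exact identities.
- Thinning keep-probabilities are compared with a 1e-12 tolerance to
  absorb float division noise in pairs↔coverage conversions.
- The evaluation problem sizes mirror the study design: 23 training and 47
  validation samples, 70 for cross-validation, full depth 4.5×, shallow
  depth 1M pairs; the accuracy grid pools 20 replicates per cell.

## Known limitations

- The estimator presumes a singleton pregnancy and a constant platform
  error rate; vanishing-twin or mosaicism scenarios violate the linear
  model.
- Aggregate-mode downsampling cannot model per-locus coverage bias, by
  construction.
- The shipped published calibration applies only to the platform
  combination it was derived on.
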