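# Methods

## The panel model

A multiplex is represented as a `PanelDefinition`: named loci, each in one
of five sample dyes (6-FAM, VIC, NED, TAZ, SID), with a repeat unit (4 nt
for tetrameric STRs, 3 nt for the trimeric D22S1045, 0 for the non-repeat
Amelogenin and Y-indel), a chromosome class (autosomal, X/Y, Y-only) and a
list of allelic-ladder bins. A bin is a labelled interval
`nominal_size ± half_width`; the default half-width is 0.5 nt, the
conventional STR bin window. Bins within a locus must be disjoint
(touching edges are allowed so that 1-nt-apart microvariants such as TH01
9.3 and 10 coexist); this makes size→bin lookup a total function with at
most one answer. Allele labels are text throughout so microvariants
("9.3", "25.2"), sex alleles ("X", "Y") and indel alleles ("1", "2") are
handled uniformly.

The built-in 24-locus panel mirrors the marker set, dye layout, repeat
units and stutter-position declarations of a contemporary six-dye casework
multiplex, but its bin coordinates are **synthetic** — integer alleles
spaced by the repeat unit from per-locus anchor sizes chosen so that every
locus fits inside the 74–444 nt read region without overlapping a
same-dye neighbour. Nothing in the package or its tests depends on real
vendor bin positions, which are proprietary.

## The electropherogram simulator

The simulator produces the peak tables a capillary-electrophoresis run
would yield, with known ground truth. For an allele of amplicon size `s`
at template input `m` pg:

    E(s) = H · (m / 1000) · φ · exp(−k·s)

where `H` is the height scale (`height_per_allele_at_1ng`, default
2000 RFU per allele copy at 1 ng), `φ` the global inhibition efficiency in
(0, 1], and `k` the degradation rate per nt (0 for intact DNA). The
realized height is log-normal with mean `E` and coefficient of variation
`cv_height` (default 0.15): strictly positive, right-skewed, and standard
in the probabilistic-genotyping literature. A homozygote contributes two
copies at one size, so its merged peak has expectation `2E`.

Heterozygote imbalance is **emergent**, not parameterized: the two alleles
of a heterozygote get independent log-normal draws, giving a mean
peak-height ratio of ≈ 85 % at cv = 0.15 (the ratio of two i.i.d.
log-normals is log-normal; E[min/max] = 2·e^{σ²}Φ(−σ√2) with
σ² = ln(1+cv²)), consistent with the >80 % means validation studies
report.

Each allele peak spawns stutter at the positions its locus declares: one
repeat unit below (minus), one above (plus, declared only for the
trimeric D22S1045), and exactly 2 nt below (declared for SE33 and
D1S1656). The stutter percentage is drawn from a normal truncated at zero
with per-(locus, position) mean and SD; the defaults come from the bundled
reference summary table (a large donor-population characterization,
n = 1092). Mixtures scale each contributor's expected heights by its mass
fraction at fixed total input; shared-allele peaks stack (heights sum) and
stutter is generated from the summed parent peaks. Same-dye peaks closer
than 0.5 nt merge with summed heights. Peaks are capped at a 30,000 RFU
saturation limit and dropped below a 20 RFU noise floor — allele dropout
at low template emerges from the height model rather than from an explicit
dropout probability.

Seeding: one master seed; per-sample generators are derived from
`SeedSequence([master, sample_index, ...])`, so extending a population or
dilution series never perturbs earlier samples, and every simulation is
bit-reproducible.

### What the generator does and does not emulate

It reproduces the statistical structure validation studies measure:
stochastic heights with realistic het imbalance, the "ski-slope" of
degraded profiles, input-proportional signal, stutter with locus-specific
magnitude, mixture ratios, and HWE population genotypes. It does **not**
model PCR cycle kinetics, inhibitor chemistry (inhibition is a single
efficiency knob), spectral pull-up, electrophoretic mobility physics, or
allele-specific stutter regression on repeat length. Passing tests
therefore demonstrate that the *analysis* layer is correct and that the
statistics recover known generator parameters — not that the generator
predicts any particular instrument's signal levels.

## Allele calling

Calling is two-stage. Stage one routes every peak by dye and size: peaks
outside the read region or below the analytical threshold (175 RFU
casework preset; 150 RFU stutter-study preset) are recorded as filtered
with their reason; in-bin peaks become called alleles; peaks inside a
locus's claim region (bin span padded by one repeat unit) but in no bin
are off-ladder; peaks claimed by no locus are dropped with a warning. The
three buckets partition each locus's peaks — no peak is lost or counted
twice.

Stage two applies per-(locus, position) stutter filters: a called allele
is reclassified as stutter when a called parent exists at the
corresponding offset and the height ratio is **at or below** the filter
percentage (the boundary convention is ≤; ties go to filtering).
Candidate parents are evaluated against the pre-filter call set, taller
first, so filtering is single-pass and idempotent — a peak that is itself
filtered still parents others, which matches how expert systems apply
static stutter filters. Cross-locus stutter is out of scope.

## Stutter measurement

Percent stutter is stutter height ÷ parent height × 100, measured on
pre-filter profiles with the stutter-study preset (parents ≥ 150 RFU,
stutter ≥ 20 RFU). Both heterozygous and homozygous parents contribute.
Three exclusion rules keep the observations unbiased, all arising from
peak stacking:

1. a stutter position occupied by a true allele yields no observation;
2. a parent sitting at a stutter offset of another true allele is skipped
   entirely (its height carries the sibling's stacked stutter);
3. a position explainable as stutter of two different true alleles (e.g.
   plus stutter of one under minus stutter of another, two repeats apart
   at the trimeric locus) is skipped as a composite.

When the donor genotype is known — the normal case in a population
characterization, and always true for simulated data — true-allele
positions come from the genotype, so tall stutter that crosses the
analytical threshold still counts as stutter. Without truth, called
alleles stand in, which slightly underestimates stutter at high-stutter
loci (SE33, D22S1045). With these rules, measured per-locus means recover
the configured generator means within ±0.12 percentage points at n = 250
donors (test tolerance ±0.3).

Summaries use the sample SD (n−1 denominator; a single observation
reports SD 0), and the filter value is the **unrounded** mean + 3·SD;
display rounding is half-up to two decimals. Recomputing mean + 3·SD from
the reference table's own rounded mean and SD columns reproduces its
printed filter column to ±0.01 for most loci; a few rows differ in the
second decimal because the original summaries were evidently computed
from unrounded internals, so exact-arithmetic checks are restricted to
loci where rounded-input recomputation is self-consistent (D22S1045,
SE33, TH01, FGA).

## Validation metrics

- **ILB** (heterozygote balance): lower ÷ higher called peak height,
  defined only for exactly two called alleles. **ICB**: per dye, each
  locus is normalized for diploidy (het peaks averaged, hom peak halved),
  then min ÷ max across the dye's loci; Y-only loci and dropped-out loci
  are excluded, and a dye with fewer than two contributing loci reports no
  value (a ratio needs two observations) rather than a vacuous 100 %.
  Both are computed after stutter filtering; on unfiltered profiles a
  homozygote plus its above-threshold stutter masquerades as a grossly
  imbalanced heterozygote.
- **Sensitivity grid**: per locus × input × replicate, heterozygous loci
  classify as full (balanced / low-ratio at the 60 % het-ratio cutoff),
  partial (one of two), or dropout; homozygous and haploid loci as full
  or dropout. Spurious alleles never upgrade a class.
- **Mixture bookkeeping**: the minor mass at ratio m:M of total T pg is
  T·m/(m+M) rounded half-up to the nearest pg (1 ng → 167 pg at 1:5,
  111 pg at 1:8). "Non-overlapping" minor alleles are evaluated per locus
  by allele label; recovery counts those present among called alleles.
- **Concordance** compares allele label sets locus by locus; it is
  symmetric and reflexive. **Sex inference** uses AMEL with DYS391/Y-indel
  redundancy: X,Y → male; X-only with a called Y marker →
  male_amel_y_null; X-only otherwise → female; no signal at all three →
  inconclusive (an AMEL-dropout profile with Y signal is also reported
  inconclusive rather than guessed).
- Replicate allele-count averages are displayed half-up at one decimal
  (or zero, matching tables that print integers).

## Probability of Identity

Per locus, under Hardy–Weinberg equilibrium,
PI = Σᵢ pᵢ⁴ + Σ_{i<j} (2pᵢpⱼ)² — the probability two random individuals
share a genotype, equal to the sum of squared genotype frequencies. The
implementation is verified against a brute-force genotype-enumeration
oracle to 1e-12 on 1000 random frequency vectors and against the closed
form (2k−1)/k³ for k equifrequent alleles. Combined PI multiplies
per-locus values over the 21 autosomal loci (in canonical locus order so
the floating-point product is permutation-invariant); Y markers are
haploid and rejected with an explanatory error. An observed-genotype
match-probability estimator (Σ of squared observed genotype proportions)
is exposed separately for sensitivity analysis, since the HWE
formulation's provenance admits variants; no minimum-frequency floor is
applied by default. Allele-frequency estimation counts two observations
per diploid locus (homozygotes twice) and one per haploid locus.

Because no empirical frequency table is bundled, population sampling uses
a synthetic, seed-deterministic frequency table: a unimodal (mid-range
heavy) Dirichlet draw per locus, AMEL fixed at X/Y = ½. Reproducing any
published combined-PI value is a non-goal; the PI machinery is validated
by oracle, not by comparison to proprietary frequency data.

## Numerical choices and problem sizes

- Log-normal draws use μ = ln E − σ²/2 so the mean (not the median) equals
  E; cv = 0 degenerates to exact heights, which the noise-free unit tests
  exploit.
- Stutter-percentage truncation at zero uses rejection sampling (the
  truncated mass is negligible at the bundled means/SDs).
- Display rounding is decimal half-up (`ROUND_HALF_UP`), not banker's
  rounding, matching how validation tables are conventionally printed.
- Property suites run at desk scale: population n = 500 donors for the
  filter round-trip (filters built from the population remove ≥ 99 % of
  ground-truth stutter peaks and no allele-origin peaks on 200 fresh
  profiles), n = 250 for stutter-mean recovery, 20 replicates × 7 inputs
  for dropout monotonicity, 50 profiles at cv = 0.05 for degradation-slope
  recovery (±10 %). The full suite completes in a few seconds.
- The dilution-series reproduction checks complete 43-allele profiles at
  1000–250 pg, near-complete (mean ≥ 42) at 125 pg, and strictly
  decreasing mean counts below. At the default height scale the expected
  het peak at 125 pg is 250 RFU against a 175 RFU threshold, so occasional
  single-allele losses there are an expected property of the height
  model, mirroring how real sensitivity series behave at the edge of the
  full-profile regime.

## Known limitations

- Off-ladder assignment uses padded bin spans; a peak falling between two
  same-dye loci belongs to neither and is dropped with a warning rather
  than guessed.
- The simulator's inhibition knob is a flat efficiency; it cannot
  reproduce inhibitor-specific locus signatures.
- Stutter magnitudes are allele-independent within a locus; real stutter
  grows with allele length, so per-locus SDs here are narrower than a
  length-stratified model would give.
- The degradation model is single-exponential in amplicon size; enzyme
  dosing units map qualitatively, not quantitatively, onto `k`.
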