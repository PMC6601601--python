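# Methods

This note records the statistical models, defaults and design choices
behind `amplisnp`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Amplicon design and read simulation

The unit of sequencing is one PCR product covering both SNPs. The shipped
default is a synthetic 119 bp amplicon with two biallelic sites 46 bp apart
(T/C and A/G, labelled rs2234693 and rs9340799 after the *ESR1* variants
whose geometry it mimics), 15 bp virtual probes centred on each SNP base,
and the Nextera transposase sequence as 3′ adapter. Real designs replace
all of this via a YAML design file; the probe pair for a SNP must differ at
exactly one position and is validated against the amplicon at load time.

Reads are single-end. Each read picks one of the sample's two template
haplotypes with a fair coin (for unphased input genotypes an arbitrary cis
phasing is used; per-SNP allele ratios are phase-invariant), optionally
runs through into the adapter (default: always, since a 119 bp insert on a
150-cycle run always reads through), then receives i.i.d. substitution
errors at `per_base_error` and Gaussian Phred qualities (mean 30, sd 5,
clipped to [2, 40]). Defaults: 20 000 reads per sample (the depth targeted
by the motivating study design) and 0.5% per-base error — a conventional
short-read figure, not a fitted instrument profile. Not modelled: indels,
paired ends, PCR duplicates, quality-dependent error rates, index
hopping. Tests and examples use depths of 150–1000 reads per sample, which
already saturate call accuracy; concordance checks use depth 500.

## Genotype calling

Pipeline per sample: adapter trim → quality/length filter → probe count →
ratio call.

- **Trimming** removes the suffix starting at a full adapter occurrence, or
  at a 3′-terminal adapter prefix of ≥ 8 bp (shorter suffixes are left:
  an 8 bp floor keeps the false-trim rate ≈ 4⁻⁸ per position).
- **Filtering** keeps reads with mean Phred strictly > 20 and length
  ≥ 100 bp. The quality rule is interpreted as a per-read mean (the
  upstream workflow this mirrors describes read selection, not per-base
  masking); the boundary is strict.
- **Counting** searches both probes of each SNP in the read and its reverse
  complement, exactly (no mismatches). Reads hitting both probes are
  ambiguous, neither: unassigned; each read contributes at most once per
  SNP. Exact matching means an error inside the probe window discards the
  read rather than miscalling it — with a 15 bp probe and error rate e, a
  fraction ≈ (1−e)¹⁵ of reads stays informative, and a wrong-allele
  assignment needs the SNP base itself to mutate to the other allele
  (probability e/3), which the ratio thresholds absorb at any realistic
  depth. A mismatch-tolerant mode exists (`match_probe(...,
  max_mismatches=1)`, assigning the strictly closer probe) but is off by
  default.
- **Calling** uses the alt-read fraction with het band (0.2, 0.8) and
  minimum informative depth 50. These cutoffs are standard amplicon-seq
  practice (a true het concentrates near 0.5, homozygotes near 0 or 1
  with leakage bounded by e/3) and are exposed on the CLI; they are not
  prescribed by the study this mirrors, which left its ratio thresholds
  unstated.

## Population genetics

Allele counts always derive from genotype counts (ref = 2·hom_ref + het).
The published frequency table this layout mirrors contains one internally
inconsistent total (an allele total of 118 where the genotype counts give
181 — consistent with a digit transposition); deriving from genotypes
avoids propagating it.

**HWE.** Pearson χ² with 1 df against expected (np̂², 2np̂q̂, nq̂²), p̂
estimated from the sample. Monomorphic sites return χ²=0, P=1 with a
warning. Known inconsistency of the published counts: the control-group
distribution of the A/G SNP (44/44/24) gives χ²=3.98, P=0.046 under this
test, while the original report states equilibrium at P > 0.05 — a claim
that holds only under an exact test (P=0.051) or with continuity
correction (P=0.065). The package keeps the uncorrected Pearson test; the
corresponding acceptance check fails honestly on that one group.

**EM haplotypes.** Standard two-locus EM over the 3×3 genotype table. Only
the double-heterozygote cell is latent; its expected cis share is
f(TA)f(CG) / (f(TA)f(CG) + f(TG)f(CA)). Initialisation is uniform (0.25
each); with a single mass of double heterozygotes and no anchoring
homozygotes the likelihood is bimodal and the uniform start breaks the tie
symmetrically — multi-start via the `init` argument if wanted. Convergence
is |Δ log L| < 1e-8 (not frequency change), capped at 1000 iterations with
non-convergence flagged, not fatal. Individuals missing either genotype
are excluded (complete case). Tests verify monotone log-likelihood,
agreement with an independent simplex maximiser to 1e-4 on n ≤ 30, and
parameter/D′ recovery at n = 2000.

**LD.** D = f(TA) − p(T)p(A); D_max = min(p(T)p(G), p(C)p(A)) for D ≥ 0,
min(p(T)p(A), p(C)p(G)) otherwise; D′ = |D|/D_max. A fixed allele makes D′
undefined and is flagged rather than coerced to 0.

**Dosages.** Expected per-individual haplotype counts; integer except for
double heterozygotes, which get the posterior cis probability. Rows sum
to 2, and at the EM fixed point mean dosage equals twice the estimated
frequency.

## Association

Logistic fits are maximum likelihood (statsmodels). Rank-deficient designs
raise immediately; separation is detected both from the optimiser and from
diverging coefficients (|β| > 25) and raised as an error rather than
returned as a huge OR. Genetic-model encodings: codominant (two
indicators, 2-df LRT — the single P spanning both rows of a codominant
block is that 2-df test), dominant, recessive, overdominant (het vs both
homozygotes), log-additive (allele count). Each model's P is a
likelihood-ratio test against the covariate-only null; per-level ORs carry
Wald 95% CIs. Default covariates: age and BMI.

Haplotype association regresses case status on non-reference expected
dosages plus covariates; reference = most frequent haplotype; haplotypes
under a 1% frequency floor are pooled into a "rare" term (at the 214-
subject study scale all four haplotypes clear the floor). In small cohorts
a rare haplotype can perfectly separate the outcome; the pipeline then
escalates the pooling floor (0.01 → 0.05 → 0.10) and finally reports the
model as not estimable while still tabulating frequencies.

Complication endpoints (CVD etc.) are analysed with the same adjusted
logistic machinery among cases. (The narrative methods of the motivating
study mention linear models for complications, but its results table
reports odds ratios; this package follows the results surface.)

Quantitative traits are transformed by a single deterministic rank-based
ordered-quantile map, Φ⁻¹((rank − 0.5)/n) with average ranks on ties,
before ANOVA — chosen over a transform-selection contest because it is
assumption-free and reproducible. Contingency-table P-values are
uncorrected Pearson χ² (this reproduces the published per-row values for
the T/C SNP; the published 0.01 for the A/G heterozygote row computes to
0.015 under this test, and the variant used there is unstated). Bonferroni
control is α/k with k = 2 SNPs by default.

## Synthetic cohorts

`simulate_cohort` draws individuals from a population model and accrues
them into arms until the configured quotas fill:

- genotypes: random union of two haplotype draws (HWE at the haplotype
  level) from (TA, TG, CA, CG) = (0.5485, 0.0216, 0.0286, 0.4013), the
  pooled estimates of the motivating study (D′ ≈ 0.91);
- age ~ N(53, 8²) truncated at 40, BMI ~ N(33, 5²);
- case status ~ Bernoulli(logit⁻¹(−7.0 + log(2.32)·1[het] + 0.10·age +
  0.05·BMI)): an overdominant effect at the first SNP matching the study's
  strongest reported association, with age/BMI confounding on by default
  (coding and coefficients configurable);
- controls must pass the fasting-glucose screen FBS < 126 mg/dl; a BMI
  floor is available but off by default (the study's BMI > 25 control
  criterion is unusual and not generally wanted);
- traits are Gaussian per arm with optional per-genotype shifts (zero by
  default, as the study found no genotype–trait association). Means/SDs
  for SBP, DBP, FBS, TC follow the study's arm summaries (SD = SE·√n);
  control-arm TG/HDL and HbA1c are not published and use typical clinic
  values (TG 150±55, HDL 45±10, HbA1c 5.3±0.4). TG is clipped below
  400 mg/dl so LDL = TC − HDL − TG/5 (Friedewald) stays valid; LDL is
  always derived, never drawn, and the identity holds exactly on the
  stored records;
- complications are Bernoulli flags among cases at the study's reported
  prevalences (CVD 10.8%, nephropathy 8.8%, diabetic foot 7.8%,
  retinopathy 5.9%), genotype-independent by default.

Default arm sizes are the study's 102 cases / 112 controls. Everything is
driven by one integer seed; the same seed reproduces cohorts and FASTQ
byte-identically.

What passing the synthetic suite shows: the estimators are correct and
calibrated under the generating model (HWE, Gaussian covariates, logistic
disease, i.i.d. substitution errors). What it does not show: robustness to
population stratification, genotyping batch effects, differential
misclassification, non-logistic disease processes or structured sequencing
error — none of which the generator produces.

## Problem sizes in tests and the acceptance script

The test suite works at desk scale: EM-vs-brute-force on n ≤ 30 cohorts;
genotyping concordance on 500 samples at depth 500 and 1% error (≥ 99%
required, and with exact probe matching the observed rate is 100%); type-I
error of the five-model LRT over 500 null cohorts of n = 200 (rejection
rate within 3 binomial SEs of 0.05); overdominant OR = 2.0 recovery over
50 replicates of n = 1000 (mean in [1.8, 2.2], CI coverage in
[0.90, 0.99]). The acceptance script uses 300 samples for concordance, 25
replicates of n = 2000 for haplotype/D′ recovery, 40 replicates of
n = 1000 for OR recovery and 200 null cohorts for calibration — sizes at
which each quantity's Monte-Carlo error is small relative to the effect
being demonstrated.

## Known limitations

- Exact probe matching discards error-bearing reads; at error rates ≫ 5%
  depth requirements grow quickly (the monotone-accuracy test maps this).
- Wald CIs and asymptotic LRTs are used throughout; no Firth/exact
  logistic, so very sparse cells surface as separation errors instead of
  estimates.
- Only two loci: no >2-SNP haplotypes, no r² (D′ only), no per-individual
  phasing output.
- The genotype caller assumes one demultiplexed FASTQ per sample.
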