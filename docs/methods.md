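# Methods

## Scope and data model

The package implements the desk-scale analysis chain for fine-mapping
GWAS-identified case-control risk loci. The unit of association testing is a
`StudyDataset` (phenotype, covariates, subjects × variants dosage matrix);
LD is computed on a phased `HaplotypePanel` (2N × L binary matrix with
1-based positions); regulatory evidence is read from local BED/TSV tracks.
Real consortium genotypes are not required anywhere: the synthetic-data
module generates study data with known truth, and two small curated tables
of published results ship with the package as worked examples.

## Synthetic data

**Haplotype panel.** Haplotypes are mosaics over a founder pool
(default 8 founders): each haplotype copies one founder and switches to a
uniformly chosen founder between adjacent variants with probability
1 − (1 − r)^d, where r is the per-bp crossover probability (default 1e-5)
and d the inter-variant gap. Founder allele frequencies are uniform on
[maf_floor, 1 − maf_floor] (floor 0.05 by default); columns whose realised
MAF falls below the floor are redrawn. This produces block-like r² decay
with distance — sufficient for testing proxy selection and conditional
scans — without coalescent fidelity: no population growth, migration,
mutation model, or recombination hotspots are represented, so passing tests
demonstrate correctness of the analysis code, not realism of human LD.

**Case-control sampling.** Disease follows
logit P = α + Σ log(ORⱼ)·gⱼ + γᵀx, with one or several planted causal
variants. Covariates are age ~ N(64.2, 9²), sex ~ Bernoulli(0.5), and
three standard-normal principal-component scores, with mild default effects
(age 0.01/yr, sex 0.15, pc1 0.05). α is tuned to the baseline prevalence
(default 0.1) by Brent root-finding on a 20,000-draw Monte-Carlo pool, then
cases and controls are drawn retrospectively by rejection sampling — cost
O(1/prevalence), with an explicit sampling-exhaustion error if a configured
draw cap is hit. The default multi-study design mirrors a consortium of 14
studies splitting 11,900 cases / 14,311 controls uniformly (850/1,022 per
study); tests use 1–3 studies of a few hundred to a few thousand subjects.

**Imputation dosages.** Hard genotypes are blurred to dosages mimicking
posterior-mean shrinkage: d = μ + Rsq·(g − μ) + ε, clipped to [0, 2], with
μ = 2p. The jitter scale is solved per variant by Brent root-finding so the
realised squared dosage-genotype correlation equals the target Rsq despite
clipping; Rsq = 1 returns genotypes exactly and Rsq = 0 returns the
constant mean (correlation reported as 0). Expected dosage preserves allele
frequency up to clipping, which is negligible at the default MAF floor.

**Annotation tracks.** Planted `EvidenceRecord`s are realised as BED
intervals (0-based half-open; by default exactly one base wide so evidence
never bleeds onto neighbouring variants) whose name field encodes
`source|cancer-or-normal|colorectal-flag`, plus a motif TSV
(variant, ref LOD, alt LOD) and a PolyPhen-class TSV. Reading the bundle
back through `evidence_from_tracks` is the identity on planted records;
records that point overlaps cannot realise (e.g. binding-in-context
inconsistent with its definition) are rejected at write time.

## Quality control

Genotyped variants drop on call rate < 0.98, control HWE P < 1e-4, or
MAF below a configurable floor. The HWE test is the exact conditional test
(probabilities of heterozygote counts given allele counts via the standard
recurrence; two-sided P sums configurations no more probable than observed,
with a 1e-12 relative tolerance for ties); a chi-square variant is provided
for speed. The exact test was chosen because the QC literature treats it as
the default and it is verifiable by brute-force enumeration. The MAF cutoff
for genotyped variants defaults to 0.005 — the published analysis states
only "low MAF", so the value is surfaced in configuration rather than
hidden. Imputed variants use the MAF-stratified Rsq rules with comparator
directions exactly as published (≤ 0.3 non-strict in the common stratum;
strict < 0.5 and < 0.99 below); the stratum boundaries are interpreted as
(0.01, 0.5], [0.005, 0.01], [0, 0.005), so MAF = 0.01 falls in the middle
stratum and the strata neither gap nor overlap.

## Association and meta-analysis

Per-study inference is maximum-likelihood logistic regression (statsmodels
Newton/IRLS; ≤ 50 iterations, 1e-8 tolerance) of case status on dosage plus
covariates. Inference is Wald — OR with symmetric CI on the log scale —
matching how such results are reported. Constant dosage, fit failure, or
|β| > 15 (separation heuristic) yield `converged=False` with a diagnostic
note; non-converged results are never silently estimated and are excluded
from meta-analysis with `k` recording the exclusion. No Firth correction or
score test is attempted. Studies (and the cancer vs adenoma strata) are
separate units combined by fixed-effects IVW; Cochran's Q with k − 1 df is
reported but never acted on (no random-effects model).

## Fine-mapping

Regions span ±250 kb around the index SNP, clipped at chromosome ends with
a truncation flag. The top SNP is the smallest meta P; ties (possible only
in synthetic data) break by larger |β|, then smaller position, then variant
id, so results are reproducible. The conditional scan refits every other
region variant with the top-SNP dosage appended to the covariates and
meta-analyses the conditional estimates; variants in perfect LD with the
top SNP (|corr| > 0.99999 on dosages) are flagged non-estimable rather than
dropped. Significance uses 0.05/#SNPs per region. Candidate selection
follows the four rules plus the conditional rule (P ≤ 5e-5 and perfect
proxies thereof). Rule-4 closure is applied once: on a fixed panel r² = 1
is an equivalence relation, so proxies of proxies add nothing. "Top 10"
counts converged, QC-passing variants only; an index SNP absent from the
scan still enters the set, flagged `index_in_scan=False`.

## LD

r² is computed on phased haplotypes by direct frequency counting,
(p_AB − p_A p_B)² / (p_A q_A p_B q_B); monomorphic variants raise an
undefined-LD error rather than returning 0. No D′, no EM for unphased data.
Perfect proxies are found exactly as equal-or-complement haplotype columns.
The r² bucketing helper uses left-closed bins with a closed top bin
([0.8, 1]) and accepts interval-coded values for published entries reported
only as "< 0.2"; for loci with several index SNPs the bucketed value is the
maximum r² over that locus's index SNPs, which reproduces the published
bucket counts.

## Functional-evidence scoring

The a-priori score sums +1 for histone modification, open chromatin,
protein binding, protein binding co-located with open chromatin or histone
marks, differing cancer-vs-normal histone patterns, and any regulatory
evidence in a colorectal cancer cell line or normal colon/rectal tissue,
plus +0.5 each for a motif LOD change strictly greater than 5 (sign
ignored) and overlap with a conserved element — maximum 7 for non-coding
variants. Possibly/probably damaging coding predictions override to 8/9;
benign/unknown coding variants score as regulatory. Categories: 3–3.5
weak, 4–4.5 moderate, ≥5 strong.

Two operationalisation choices were genuinely open. (a) For track-derived
evidence, the cancer/normal differential fires when histone overlap status
disagrees between any cancer-tagged and any normal-tagged source (a
presence/absence XOR); count-difference thresholds were deliberately not
used since no quantitative rule is published. (b) The curated candidate
table prints histone counts by source but no per-variant differential
indicator, and a presence/absence XOR on printed counts contradicts the one
published per-row worked score; the curated encoding therefore leaves the
differential component unset, computing scores from the printed columns
only — all 21 rows reach the strong category regardless. Single-source
overlap suffices for every boolean (the published table contains
single-cell-line strong candidates).

Gene context assigns variants inside a gene body to that gene (exonic by
exon overlap, else intronic); intergenic variants go to the gene with the
nearest transcript end, labelled 5′/3′ relative to that gene's strand, with
name-ordered tie-breaking. No enhancer-skipping or eQTL logic.

## Power

Two-sided Wald power for the per-allele trend test with
Var(β̂) ≈ 1/(2·n_cases·p₁q₁) + 1/(2·n_controls·p₀q₀), where the case allele
frequency follows from the per-allele OR at the allele level and controls
sit at the population frequency. The minimum detectable OR inverts the
power function by Brent root-finding to 1e-6. The published "80% power for
OR 1.12 at MAF 20%" figure does not state its alpha; a per-region
Bonferroni alpha of about 0.05/1807 ≈ 2.8e-5 reproduces 1.12 closely, so
the package documents that as a calibration observation without asserting
it was the original choice.

## Pipeline

Stages exchange files: phased panel and per-study dosages as VCF (GT + DS,
AF/RSQ/TYPED in INFO), phenotypes and all results as headered TSV
(association columns LocusZoom-compatible), tracks as BED/TSV. Coordinates
are 1-based inclusive internally; BED I/O converts at the boundary. A
single YAML config drives all thresholds and the seed; the manifest records
per-stage counts and sha256 checksums, and reruns are byte-identical under
a fixed config. Study dosages are written with three decimals, so the
file-driven pipeline quantises dosages at 0.001 — immaterial at the demo
scale (default: 3 studies × 300/300 subjects, 120 variants, one region).

## Test-suite problem sizes

Stochastic suites run at reduced scale chosen to keep Monte-Carlo error
well inside the asserted bands: type-I error from 800–1,000 replicates at
n = 1,000; CI coverage from 60 replicates at 1,500–2,000 cases/controls;
conditional family-wise error from 30–40 replicates on 30-variant regions;
two-signal detection from 20 replicates at 2,000/2,000; Cochran's-Q
calibration from 2,000 replicate meta-analyses; dosage-degradation accuracy
at n = 5,000. Hypothesis-based property tests are derandomised.

## Known limitations

No sample-level QC, no imputation algorithm (dosage error is emulated), no
population-structure simulation beyond synthetic PCs, no random-effects
meta-analysis, no Bayesian credible sets or summary-statistic conditional
analysis, no live annotation-database queries, and no eQTL or splice-site
integration. The founder-mosaic LD model underestimates the heterogeneity
of real human LD, so simulation-based power figures transfer to real data
only approximately.
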