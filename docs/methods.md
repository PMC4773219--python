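# Methods

`rarecnv` implements a rare copy-number-variant (CNV) discovery workflow
for case-control cohorts genotyped on SNP arrays, in the setting of
hypertension-related left-ventricular hypertrophy (LVH): cases are
hypertensive patients with LVH, controls hypertensive patients without.
The working hypothesis is that individually rare CNVs disrupting genes
contribute to disease susceptibility, so the analysis is built around
stringent filtering down to CNVs that are unique to the study — and then
to one group — rather than around common-variant association.

## Phenotype model

Left-ventricular mass is estimated from M-mode echocardiography with the
Devereux-corrected cube formula

    LVM = 0.8 · {1.04 · [(LVIDD + PWTD + IVSTD)³ − LVIDD³]} + 0.6 g

with LVIDD (LV internal dimension in diastole), PWTD (posterior wall
thickness) and IVSTD (interventricular septal thickness) in cm. The factor
1.04 g/cm³ is myocardial density, 0.8 the regression shrinkage of the
anatomically validated cube estimate, and +0.6 g its additive correction
(parameterized, since source texts occasionally garble it). The LV mass
index (LVMI) is LVM / height², with height in m. LVH is diagnosed when
LVMI *strictly exceeds* 110 g/m² in women or 125 g/m² in men; a value
exactly at the threshold is not LVH. Cohort tables compare continuous
variables with Welch's two-sample t-test and sex with a chi-square test
(Fisher's exact at expected counts < 5); the tests are deliberately
assumption-light because the summaries are descriptive.

## Sample quality control

Per-sample array quality uses four metrics with strict exclusion
directions (boundary values pass):

| metric | definition | excluded when |
|---|---|---|
| call rate | fraction of probes with a genotype call | < 0.99 |
| LRR SD | SD of autosomal log R ratio | > 0.35 |
| BAF SD | SD of B allele frequency over the heterozygous band [0.25, 0.75] | > 0.13 |
| batch ratio SD | SD of per-probe intensity ratio / batch median profile | > 0.27 |

Two estimator choices deserve note. The BAF SD is restricted to the
heterozygous band because the homozygous clusters at 0 and 1 would
dominate a full-range SD and make a 0.13 threshold meaningless; the
band-restricted statistic saturates near 0.144 (the SD of a uniform
variable on a width-0.5 interval), so 0.13 sits close to the ceiling and
effectively asks that the heterozygous cloud be coherent at all. The
"cross-sample batch-normalized ratio SD" has no published formula; our
surrogate divides each sample's per-probe intensity ratio by the batch
median profile (removing shared probe effects) and takes the SD of the
quotient. Both are configurable.

After consensus calling, samples whose aggregate CNV length is an upper
outlier are excluded: the fence is the Tukey rule Q3 + 3·IQR over the
currently kept samples, chosen for being robust, deterministic and
parameter-light; a sample with no calls contributes 0 and can never be an
upper outlier, and with fewer than 4 samples no test is performed.

## Consensus calling and interval filters

Calls from three detection algorithms are merged within each (sample,
chromosome, gain/loss) stratum by **single-linkage clustering at 50%
reciprocal overlap**: two intervals are linked when their intersection
covers at least half of *each*. A cluster becomes a "stringent" consensus
call when at least 2 of the 3 algorithms support it; its interval is the
cluster's outer bounds (conservative for downstream overlap tests; the
intersection and median boundary rules are available as configuration,
since merge semantics are genuinely underdetermined). Exact duplicate
calls collapse with a warning.

Consensus calls are then excluded when they (i) contain fewer than 5
manifest probes, (ii) have length-weighted mean GC over the overlapped
track windows above 0.70, (iii) lie within 30 kb of a centromere or
telomere interval, (iv) are shorter than 1 kb (exactly 1 kb is retained),
or (v) sit on a sex chromosome. The 30 kb margin implements "approximately
30 kb" as a strict gap threshold and is configurable. Calls longer than
1 Mb receive a review flag rather than automatic exclusion — a stand-in
for the manual inspection such calls get in practice, since automation
cannot reproduce visual curation; an optional hard cap can exclude them.
Every filter stage reports a conserving tally (input = retained +
excluded, multi-reason calls counted once in the total and once per
reason in the breakdown).

## Rarity, specificity, recurrence, burden

A filtered call is assessed in the fixed order:

1. **Common polymorphism (CNP) rule** — excluded on any overlap (≥ 1 bp)
   with a reference variant whose population frequency exceeds 1%.
2. **Reference-overlap rule** — excluded on ≥ 50% reciprocal overlap with
   any variant in the reference sets (a DGV-like catalogue plus
   HapMap3-like and SGVP-like population sets, applied in order). The
   boundary at exactly 50% counts as known, because the natural-language
   rules ("kept if < 50%", "excluded if > 50%") contradict each other at
   the boundary; the fraction is a parameter.
3. **Singleton rule** — calls whose cross-sample occurrence cluster (same
   linkage as the merge) spans ≥ 2 distinct samples are marked
   non-singleton.

The rules are recorded separately so tallies are auditable. Case/control
specificity operates on the calls surviving rules 1–2 (both the singletons
and the cohort-recurrent ones): a call is group-specific when no
opposite-group consensus call of the same type links to it at the 50%
reciprocal-overlap linkage, tested conservatively against the *entire*
retained consensus set of the other group, not just its rare calls.
Recurrent loci are then linkage clusters of case-specific calls spanning
≥ 2 distinct case samples, reported with outer-bound locus and the genes
they disrupt. Keeping non-singleton calls in the specificity candidate
set is what allows recurrent case-only loci (observed in 2–3 cases) to
be reported at all; a strict singletons-only reading would make
"recurrent case-specific CNV" a contradiction in terms.

Gene disruption is any ≥ 1 bp intersection with a gene model
(containment-only is available); calls disrupting nothing render as a
dash in reports. The burden report gives per-group totals, gain/loss
splits (always summing to the totals), per-genome means (group total /
group genome count), length means/medians, a size-bin percentage
histogram, and a case-vs-control length comparison (Welch's t-test by
default, Mann-Whitney optionally; identical samples short-circuit to
statistic 0, p = 1).

## The synthetic study generator

No raw data accompany the modelled study design, so the generator is a
first-class module that emulates every input at desk scale, with a
**truth ledger** enabling exact recovery checks.

* **Genome scaffold** — by default chr1 (40 Mb), chr2 (30 Mb) and chrX
  (12 Mb) with mid-chromosome centromeres (2 Mb), 50 kb telomeres, a
  10 kb-windowed GC track (baseline N(0.42, 0.05) clipped below 0.70,
  with a 1% rate of high-GC windows at 0.72–0.80 so the GC filter is
  exercised), ~20,500 probes at 4 kb spacing, and 200 random gene models.
* **Cohort** — 44 cases / 72 controls, the analysis cohort size of the
  modelled design. Echo measurements are drawn from group-specific
  distributions (case LVMI centred near 143 g/m², control near 58) and
  rejection-sampled until the phenotype classifier reproduces the
  intended label, so the phenotype loop closes exactly at error rate 0;
  a configurable error rate flips labels.
* **Planted CNVs** — 30 CNP loci with frequencies uniform on
  (0.02, 0.40) assigned to samples by per-locus Bernoulli draws; 5 rare
  loci shared by one case and one control (never group-specific by
  construction); Poisson singletons per genome (rates 2.0 case / 1.7
  control); and recurrent case-only loci carried by exactly 3, 2 and 2
  distinct cases, mirroring the recurrence pattern the design reports.
  Lengths are uniform on 30–120 kb. All loci are placed in callable
  autosomal space: ≥ 50 kb from each other and from
  centromeres/telomeres, clear of high-GC windows over a padded span,
  and with ≥ 5 probes remaining after worst-case breakpoint jitter — so
  planted loci survive the interval filters by construction and
  recovery failures indicate pipeline defects, not placement accidents.
* **Reference sets** — every CNP locus enters the DGV-like set with its
  true frequency (subsets enter the population sets); 40 decoy variants
  are placed in free space so they can never shadow a planted rare locus.
* **Calling algorithms** — three labelled emulators emit each true CNV
  with per-algorithm sensitivity, endpoints independently jittered by
  ± jitter·length (clamped to the chromosome), plus Poisson false
  positives per genome drawn away from every planted locus so
  true/false provenance is unambiguous. Defaults are sensitivity 0.95,
  10% jitter and 2 FPs/genome — a deliberately imperfect operating
  point; the noiseless limit (`config.noiseless()`) is the closed-loop
  validation condition. At 50% linkage the jitter is harmless by
  construction: two jittered copies of one locus always retain
  reciprocal overlap ≥ 0.8/1.2 ≈ 0.67.
* **QC signals** — per-sample LRR/BAF/call-flag/intensity-ratio vectors
  over 4,000 autosomal probes (clean samples: call rate 0.995–0.999,
  LRR SD 0.10–0.20, het-band BAF SD 0.02–0.04, ratio SD 0.05–0.15, plus
  a shared per-probe ratio profile that batch normalization removes).
  Failure injection (default rate 0) pushes exactly the chosen metric
  over its bound; an injected BAF failure scatters BAF uniformly, whose
  in-band SD approaches the 0.144 ceiling and clears 0.13 reliably.

Everything is driven by one seed; identical (config, seed) reproduces
byte-identical outputs including the ledger, and serialized run manifests
deliberately omit wall-clock timestamps to preserve that property.

### What the simulation does and does not show

Passing the closed-loop and noisy-recovery checks shows that the
*pipeline logic* — merging, filtering, rarity bookkeeping, specificity,
recurrence — is correct against a known truth under realistic call-level
noise. It does **not** validate the upstream detection algorithms
(segmentation HMMs are out of scope; the generator emulates their
output), nor artifacts real arrays exhibit that the generator omits:
GC-wave in LRR, batch-correlated breakpoint errors, systematically
shared false-positive regions between algorithms, population structure
in CNP frequencies, or mosaicism. Planted loci deliberately avoid the
filterable genome, so the filter stages remove only false positives
here, whereas on real data they also sacrifice true calls in bad
regions.

## Numerical and design choices

* Coordinates are 0-based half-open internally; rawcnv and DGV-style
  files are 1-based inclusive on disk, BED-flavoured files half-open.
  Conversion happens only at the I/O boundary and round-trips exactly.
* Chromosome labels normalize to `chr1`…`chr22`, `chrX`, `chrY`; bare
  `1`/`X` are accepted on input, anything else is a counted record-level
  error (whole-file failures are reserved for unparseable mandatory
  fields, reported with line numbers).
* All threshold comparisons use the documented strict directions; QC and
  filter boundary cases are pinned by tests at one-ulp resolution.
* Sample SDs use the n−1 denominator; constant vectors return exactly 0.
* The per-genome mean is reported as the exact ratio (rendered at 2 dp
  with standard rounding).
* Degenerate statistics short-circuit: identical groups give
  statistic 0 / p 1 rather than NaN from a zero-variance test.
* Interval indices (reference sets, gene models) are interval trees;
  single-linkage clustering runs on a start-sorted sweep with union-find
  and is validated against exhaustive partition enumeration for n ≤ 8.

## Problem sizes

The default simulated study — 116 samples, ~20,500 probes, ~950 planted
CNVs, ~3,500 emitted calls — runs through the full pipeline in a few
seconds; the package's validation suite, including two full-scale
simulated studies and the brute-force oracle comparisons, completes in
well under a minute. Full-genome scale (more and longer chromosomes,
denser manifests) is purely a configuration change.

## Known limitations

* The batch-ratio QC metric is a documented surrogate for an undefined
  vendor statistic; absolute threshold semantics on real data may differ.
* Manual curation of very large calls is replaced by a review flag; the
  pipeline cannot reproduce judgement-based exclusions.
* The reference-set schema is generic (id, interval, type, frequency);
  provenance details of real catalogues (study counts, platforms,
  genome build lineage) are out of scope, and inputs are assumed to be
  on one consistent build.
* Pathway/ontology enrichment and wet-lab validation of candidate loci
  are out of scope by design.
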