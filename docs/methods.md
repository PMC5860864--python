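# Methods

## Scope and data model

`uroseek` operates downstream of sequencing: its mutation-level input is the
UID-family count table (per patient, assay, well and queried position: mutant
and total UID families), and its copy-number input is the locus-by-sample
count matrix of a repeat-amplicon assay whose loci tile the 39
non-acrocentric autosomal chromosome arms. Raw read processing, UID
collapsing and alignment are out of scope.

Two assay families are modelled: a ten-gene multiplex hotspot panel
(TP53-heavy, as in urothelial tumours) and a TERT promoter singleplex
restricted to the three hotspots g.1295228, g.1295250 and g.1295242 (hg19,
chr5). Every sample is assayed in two independent PCR wells per assay.

## Mutation calling

The caller is calibrated entirely from normal controls:

1. **Per-mutation normalisation.** For each queried position, control WBC
   MAFs define a robust location (median) and scale (MAD × 1.4826). The
   scale is floored at `max(0.2/N, 1e-6)`, N the total number of control
   observations, so that positions whose controls are all zero still get a
   finite, small scale. Rationale: error rates vary strongly by sequence
   context, so the evidence in a given MAF can only be judged against that
   position's own error distribution.
2. **Pooled empirical null.** All normalised control values (every key, both
   wells of every control) form one sorted null; a sample well's normalised
   score gets the one-sided add-one-smoothed p-value
   `p = (1 + #{null ≥ s})/(N + 1)`, so p is never 0 and the subsequent
   normal inversion is finite.
3. **Stouffer combination.** `z = Φ⁻¹(1 − p)` per well, combined with
   weights `w = √UID` (the information in a proportion grows with the
   number of templates; its z-scale weight is the square root). A literal
   `w = UID` mode is available by configuration.
4. **Two criteria.** A candidate (≥ 2 mutant UID families in *both* wells)
   is positive when either the difference statistic exceeds `t_diff` (the
   highest MAF at any position in any control WBC — a global threshold,
   while the subtracted per-key maximum is mutation-specific) or the
   Stouffer Z exceeds `t_z`. `t_z` is the second-largest per-sample maximum
   Z among the 188 control urines with "positive" meaning strictly greater,
   so exactly one control urine is positive by construction — the designed
   technical false-positive budget of the test. On independent control
   panels the expected count is ~2 of 188 (the classical `m·k/(n+1)`
   exceedance rate for an order-statistic threshold).

The candidate floor of two mutant families per well is plumbing: singleton
UID-family errors are ubiquitous and carry no callable signal.

Identity checking compares genotype calls at 31 common SNPs (chromosomes 10
and 20) between paired samples; a matching fraction below 0.90, or fewer
than 10 comparable SNPs, flags a potential sample mix-up. The 0.90 cutoff is
a package choice (configurable).

## Aneuploidy scoring

Arm shares of total depth are standardised against a euploid reference
(per-arm mean and SD across euploid control profiles). An arm is called
gained or lost when |z| exceeds a threshold set at the 99th percentile of
euploid training |z| (a 1% per-arm call budget; the assay publishes no
arm-level cutoff, so this is a package choice).

The genome-wide score is an RBF-SVM trained on 3,150 synthetic aneuploid
samples (1–5 random arm events at neoplastic fractions log-uniform in
[0.005, 0.10]; a single-copy event scales an arm's expected share by
1 ± nf/2 on a diploid baseline) and 677 euploid samples, both drawn
parametrically from the fitted euploid reference so each carries exactly one
multinomial draw of counting noise, like a real profile. Three calibration
choices matter:

* **Order-statistic features.** The SVM sees `sort(|z|, descending)` rather
  than the raw 39-vector: aneuploidy means "some arms are extreme,
  irrespective of which", and sorting aligns that signal onto fixed
  coordinates where a kernel can resolve it. Raw-z kernels must either
  memorise arm identities or blur single-arm spikes into the euploid cloud.
* **Balanced SVM classes.** The 3150/677 ratio is a training artefact;
  without balancing it leaks into the calibrated score as a prior of ~0.82
  for any ambiguous sample.
* **Specificity-first Platt scaling.** Decision values from 5-fold
  out-of-fold prediction are mapped to [0, 1] by logistic regression with
  the euploid class up-weighted (default 8×), so a score of 0.7 corresponds
  to spike evidence clearly outside the euploid range. The assay is
  specificity-first by design (its published technical specificity is
  essentially perfect); the cost is sensitivity only within ~1.5× of the
  detection limit.

A sample is positive when score > 0.7 (strict) *and* ≥ 1 arm is called. The
trained model serialises to a single JSON file (reference, support vectors,
kernel and Platt coefficients) and reloads bit-stably without retraining.

Under the default synthetic conditions (median depth 8×10⁶ over 3,900 loci)
the single-arm-gain detection curve crosses 50% at a neoplastic fraction of
~1.5–2%, with euploid profiles above 0.7 in <1% of cases.

## Assay combination and evaluation

The combined test is a logical OR of the three assay flags; adding cytology
is again an OR, with the equivocal "atypical" category counted as
non-positive and patients without cytology excluded from combined-subset
metrics (but kept in assay-only metrics).

Confidence intervals default to the modified Wald (Agresti–Coull) form with
z = 1.96; an exact Clopper–Pearson mode is provided. Lead time converts days
to months at 30.44 days/month. False-negative attribution splits
urine-negative cancers by whether the tumour carries any queried mutation
("insufficient cells" vs "no queried mutation"). Substitution spectra fold
onto the six pyrimidine-strand classes; the A:T>T:A fraction (the T>A class)
is reported per gene because it is the signature of aristolochic-acid
exposure relevant to upper-tract disease.

## The synthetic cohort generator

The generator defines the study conditions the pipeline is tested under:

* **Background errors.** Each queried position receives a persistent
  position-specific error rate, Gamma-distributed (shape 1) around 1e-4 per
  UID family; per well, mutant families are Gamma-Poisson (shape 5)
  around `total × rate`. The persistent per-position component is the reason
  per-mutation normalisation exists; the per-well component gives the null
  heavier-than-binomial tails.
* **Depths.** UID families per position per well: log-normal, median 10,000
  (σ = 0.5). Locus totals: log-normal, median 8×10⁶ (σ = 0.25) over a
  default 3,900 loci (100 per arm; the full-scale 38,000 is a configuration
  change — 3,900 keeps desk-scale runs fast at equal per-arm information
  granularity).
* **Cases.** 95% of case tumours carry ≥ 1 queried mutation (TERT with
  probability 0.65, gene draw TP53-weighted); shedding is two-stage — the
  tumour is mutated, then with probability 0.8 the urine contains
  assay-detectable tumour DNA — so both false-negative modes (no queried
  mutation vs insufficient neoplastic DNA) arise naturally. Planted urine
  fractions are log-normal with median 8% (multiplex) / 6% (TERT), σ = 1.1,
  clipped to [0.003, 0.8]. Aneuploid tumours (90% of cases) carry 1–5 arm
  events biased toward 5q, 8q and 9p, at neoplastic fractions log-uniform
  in [0.002, 0.30].
* **Cohorts.** Early detection 570 patients / 175 cancers, upper-tract 56 /
  56, surveillance 322 / 187 — assigned exactly, shuffled by seed. Cytology
  availability ~61–75% with category rates chosen so cytology is ~43%
  sensitive (early detection) and never falsely positive; diagnosis delays
  are log-normal (median 40 days, σ = 1.1), giving mean lead times of a few
  months with a small tail beyond a year.
* **Non-cases.** 5% of non-cases carry a low-fraction clonal mutation
  (median MAF 1%), emulating the biological false positives of urothelium.

Identical configuration and seed give bit-identical outputs (all randomness
flows from one `SeedSequence` tree; per-patient streams are keyed by CRC of
the patient identifier).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-context error structure beyond a static
per-position rate (no batch or run effects), locus-level amplification drift
between samples (locus weights are fixed per panel), sub-arm and focal copy
number change, tumour heterogeneity and private urine clones (urine
mutations are always a subset of tumour mutations unless planted otherwise),
and clinical covariates beyond labels.

## Numerical choices and degenerate inputs

* Empirical p-values are add-one smoothed; zero p is impossible by
  construction, and `stouffer_combine` rejects p ≤ 0 defensively.
* Wells with zero total UID families are excluded (MAF undefined) and the
  position simply cannot become a candidate in that sample.
* Metrics with zero denominators are reported as NaN and named in
  `undefined`, never silently zeroed; CIs are clipped to [0, 1].
* Ties in the calibration order statistic are broken by the strictly-greater
  rule; continuous UID weights make exact Z ties measure-zero.
* The euploid reference SD is floored at 1e-12; arm maps must cover all 39
  arms with ≥ 10 loci each.

## Known limitations

* The genome-wide aneuploidy score is a faithful re-implementation surface
  (SVM over arm z-scores, calibrated to [0, 1], 0.7 decision threshold), not
  a byte-level reproduction of the published classifier, whose exact
  construction and training corpus are external.
* Whether the pooled mutation null should collect raw or normalised MAFs is
  ambiguous in the source description; normalised values are used, which
  makes the null exchangeable across positions.
* The per-arm z-score ignores within-sample GC/locus normalisation; under
  the generator's fixed locus weights this is exact, on real data it is an
  approximation.
* Cohort-level sensitivities depend on the generator's shedding and MAF
  assumptions; they are conditions, not claims about any particular patient
  population.
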