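# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `shhscreen`, in the order of the pipeline stages. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Plate-screen scoring

### Model and assumptions

A dual-luciferase screen measures, per well, a pathway-responsive firefly
luciferase (Fluc) and a constitutive Renilla luciferase (Rluc) transfection
control; the raw signal is the ratio Fluc/Rluc. The scoring model treats
every systematic influence on the ratio as multiplicative: a per-plate
scale factor, a peripheral (edge) bias, the cDNA's true effect, and
positive well-level noise. Under that model, dividing every well by its
plate median removes the plate factor exactly and buffers spatial artifacts
and outliers, which is why all downstream scores are invariant to rescaling
any plate (tested as a property).

Scoring steps:

1. wells with missing, zero or negative Rluc are dropped and counted, never
   imputed;
2. each well's ratio is divided by the plate median;
3. normalized values are averaged per cDNA, pooling wells across plates and
   treatment arms (see below); cDNAs with fewer than `min_wells` (default
   8, one plate row of technical replicates) are flagged and excluded;
4. z-scores standardize each cDNA's mean activity against the set of all
   screened cDNAs, using the sample SD (ddof = 1); the "deflection" is the
   activity centered to the cDNA-set mean, so deflection and z always share
   a sign;
5. hits at z ≤ −strong_z (inhibitor) or z ≥ strong_z (activator), default
   strong_z = 2, boundaries inclusive; a weak flag at |z| ≥ weak_z
   (default 1) feeds the two-screen rule.

Choices where the procedure was genuinely open:

* **Controls (GFP) are excluded** from the mean/SD defining z: the
  reference set is the screened cDNA collection; controls serve QC (their
  normalized activity is reported in the results summary).
* **Pooled-well averaging** is the default (the mean over all of a cDNA's
  wells) rather than averaging per-plate means; for the balanced layouts
  the simulator produces the two coincide.
* **Multiple agonist doses** (e.g. two SAG concentrations run as separate
  arms) are pooled into one screen by averaging normalized values; running
  arms as separate screens and merging at the concordance step is equally
  supported by scoring each arm's table separately.
* **Linear, not log, scale** for z: activities are already ratios of the
  same order of magnitude after plate centering, and the choice is pinned
  by tests.

Cross-screen concordance: the union hit set contains cDNAs that are strong
hits in either screen plus cDNAs weak in both; members are classified
concordant (inhibitor/activator) or discordant by sign agreement. A cDNA
scored in only one screen, or with an exactly zero z, is `not_called`.

### Numerical note on scale invariance

Plate rescaling cancels algebraically, but IEEE floating point does not
guarantee `(c·x)/(c·m) == x/m` at the bit level for arbitrary `c`. The
invariance tests therefore assert bit-identity for power-of-two constants
(whose multiplication is exact) and 1e-12 relative agreement for arbitrary
positive constants.

## Secondary-assay statistics

Alkaline-phosphatase absorbance is median-centered per plate with the same
contract as the luciferase ratios. Each cDNA is compared to the control on
the pooled ranks of **all** groups: the global Kruskal–Wallis H
(tie-corrected, via scipy) is reported, and Dunn's post-hoc statistic

    z = (R̄_control − R̄_cdna) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_c + 1/n_i)]

with T = Σ(t³ − t) over tie groups gives a two-sided normal p per cDNA.
The tie correction is included because absorbance readings tie after
instrument rounding. Only ranks enter, so any strictly monotone transform
of the values leaves every p unchanged (tested).

**Two-stage FDR (Benjamini–Krieger–Yekutieli).** Stage 1 runs the linear
step-up procedure at the adjusted level α′ = α/(1+α) and estimates the
number of true nulls m₀ = m − r₁; stage 2 reruns the step-up at
α′·m/m₀ (rejecting nothing if r₁ = 0, everything if r₁ = m). The
`significant` flag is this exact decision. q-values are defined by
inversion — the smallest level at which the two-stage procedure rejects
the hypothesis — computed by bisection to 1e-6 and forced monotone
non-decreasing in p; only their threshold behavior (q < 0.1, q < 0.05) is
load-bearing. The rejection set is verified in tests against both an
independent loop-based evaluation of the definition and statsmodels'
`fdr_tsbky`.

A caution documented here because it is easy to assume otherwise: the
two-stage procedure is *not* uniformly more powerful than plain
Benjamini–Hochberg at the same α. Example: m = 2, p = (0.024, 0.9),
α = 0.05 — BH rejects one hypothesis, but stage 1 at α′ = 0.0476 rejects
none, so the two-stage procedure stops with zero rejections. On typical
inputs it dominates BH, and the test suite asserts the dominance on its
frozen random vectors, but it is not a theorem.

Viability time courses are summarized by the trapezoidal area under the
curve over the observed interval (points sorted by time; duplicate
timepoints are an error). Comparisons of AUCs between cDNAs are delegated
to standard ANOVA machinery and are out of scope here; the package supplies
the AUC construction and the FDR layer. The FDR family is per assay (all
cDNA-vs-control comparisons within one assay), not across assays.

## Dosage expression

### Quantities

* **Exon-union length** (`genelen`): total bases covered by the union of
  all exon intervals, counting overlaps once (merge sweep; verified against
  a per-base incidence oracle). Coordinates are 0-based half-open
  throughout; BED12 is native, GFF3 is converted on read.
* **Length normalization**: `len_norm = 50 × readcounts / genelen`. The
  constant 50 matches a 50 bp read-length scaling and is implemented
  verbatim; a gene whose read count equals its exon-union length returns
  exactly 50.
* **Ortholog aggregation** (transchromosomic genotypes): all rows are
  length-normalized, then each human row is added onto its mouse-ortholog
  row. The merge conserves signal exactly (merged = sum of species inputs,
  tested bit-exactly) and reports the human-derived fraction per gene.
  Human genes without a mouse partner are reported separately and excluded
  from fold-change profiles.
* **Size factors**: per-sample median, over genes with nonzero counts in
  every sample, of the count divided by the gene's geometric mean across
  samples (median-of-ratios).
* **Fold change**: ratio of trisomic to euploid genotype means of
  normalized counts. A pseudocount (default 0.5) is added to both group
  means *only* when the euploid mean is zero but the gene passes detection,
  so typical genes are exact and division by zero cannot occur.
  "Detectable" means a nonzero count in at least half the samples of either
  genotype (configurable). Dosage bins: below < 1.3, central [1.3, 1.7]
  (closed on both ends, pinned in tests), above > 1.7, undetected.
* **FPKM/TPM** use the standard definitions (FPKM = 10⁹·rc/(len·total);
  TPM normalized to 10⁶ over the gene set) and exist only as detection
  evidence. The detection filter excludes a gene only when it fails all
  three lines of evidence — not detected in the experiment's RNA-seq AND
  every supplied external FPKM < 1 AND every supplied external TPM < 1; a
  single value at or above the cut rescues the gene.

### Normalization reference set

With a sizable fraction of genes dosage-shifted in one direction (one fifth
of the genes in the standard synthetic design), median-of-ratios size
factors estimated over *all* genes absorb part of the trisomy signal —
factors for trisomic samples are pulled up, euploid factors down — and mean
trisomic fold changes are biased from 1.5 toward ~1.40. `DosageExperiment`
therefore estimates size factors on the disomic genes by default, which in
an aneuploidy study are known a priori from the model's genetic map. This
is the standard aneuploidy-aware normalization; the plain all-gene
estimator remains available (`size_factor_genes="all"`), and with a small
trisomic fraction (as in a ~14,000-gene transcriptome) the two coincide for
practical purposes.

The remaining small upward bias of the *mean* fold change (ratio-of-means
estimators satisfy E[X/Y] > E[X]/E[Y]) is visible in the recovery tests as
means slightly above 1.5 and is inherent to the statistic, not corrected.

## Candidate prioritization

Per-screen z-scores are averaged over the screens in which a gene was
scored (imputing 0 for unscored screens is available behind a flag but not
default). The differentiation screen contributes a z computed exactly like
the reporter screens — plate-median-centered alkaline-phosphatase activity,
z over the cDNA set — with reduced differentiation negative, i.e.
inhibition. Direction is the sign of the average z, `mixed` when per-screen
signs disagree and |average z| is below the weak threshold. Trisomy flags
come from interval membership: a gene is trisomic in a model iff its start
position falls inside a trisomic segment and outside any nested deletion
(0-based half-open: a gene starting exactly at a segment end is outside).
Genes without coordinates (e.g. human-specific genes with no mouse
ortholog) are handled through explicit membership lists. Ranking filters to
detection-retained genes and sorts by average z (ascending for inhibitors),
breaking ties by the number of screens scored, then lexicographic gene id.

## Synthetic data generators

### What they emulate

* **Plates**: 8×12 plates, dedicated control rows (default 2 full rows of
  GFP wells, 24 wells per plate), one row of 8 replicate wells per cDNA;
  log-normal multiplicative structure — per-plate scale factor
  (log-scale SD 0.15), mean-one well noise (CV 0.10), and a multiplicative
  elevation of peripheral wells (first/last row or column; +5% by default).
  The underlying study does not report these magnitudes; the defaults are
  plausible for luminescence plate assays and are exposed in the config.
  Log-normal noise was chosen because ratios are strictly positive and all
  modeled effects are multiplicative. Rluc is simulated with its own noise
  and Fluc is derived from the target ratio, so the ratio carries exactly
  the configured structure.
* **Counts**: negative-binomial counts (var = μ + α·μ², `dispersion` = α,
  default 0.05; α = 0 gives the deterministic rounded-expectation limit)
  with per-gene expectation ∝ relative abundance (log-normal, log-SD 1.0)
  × exon-union length × copies/2 × per-sample library factor (log-normal,
  log-SD 0.1), scaled so a euploid sample's expected total equals
  `library_size`. The default design is 4 trisomic vs 4 euploid samples.
  Expected expression is strictly copy-proportional, so every 3-copy gene
  has a true fold change of exactly 1.5. Trisomic genes occupy a dedicated
  chromosome segment (supporting segment-membership mapping downstream);
  deletion segments reset genes to two copies. In transchromosomic mode the
  mouse row keeps two copies while the third copy is emitted as a
  human-tagged row with the same exon-union length, so expected expression
  splits 2:1 between species and the species-summed expectation equals the
  freely-segregating simulation exactly.

Both generators draw from a single seeded `default_rng` stream and are
bit-reproducible; the seed is recorded in the pipeline manifest.

### What they do not emulate

Luminescence photon statistics, transfection-efficiency covariates, cell
growth, smooth (non-step) spatial gradients, batch effects between
experiments, correlated gene expression, 3′ bias or mappability variation,
GC effects, and isoform-level complexity. Passing the recovery tests
therefore demonstrates that the estimators are correct under the stated
multiplicative/NB model, not that real screens are free of artifacts the
model omits.

## Problem sizes used by the tests

The suite exercises the estimators at sizes where the Monte-Carlo
tolerances are meaningful but the whole run stays fast: 200 simulated null
screens of 163 cDNAs for calibration (the |z| ≥ 2 call fraction is compared
to the ~4.6% two-sided normal tail), 100 spiked screens for power, 500-gene
/ 100-trisomic count matrices for dosage recovery (±0.05), exhaustive
p-value grids up to length 5 plus 1,000 random vectors for the FDR oracle,
and 50 seeded end-to-end pipeline runs for candidate recovery.

## Known limitations

* Differential-expression significance testing (shrinkage GLMs, Wald
  tests), GO/GSEA enrichment, PCA visualization, and read alignment /
  transcript assembly are out of scope; the dosage module stops at fold
  changes and summaries.
* q-values are defined operationally by inversion of the rejection rule;
  between-threshold values inherit the bisection tolerance (1e-6).
* The edge-gradient model is a step function on peripheral wells; no
  B-score/median-polish spatial correction is applied.
* The ranked candidate table orders genes by average z only; it does not
  model between-screen weighting or measurement error in the average.
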