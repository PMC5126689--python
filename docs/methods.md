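# Methods

`lincsig` implements a two-stage analysis of lincRNA expression in paired
tumor/normal cohorts, together with downstream regulatory and clinical
association analyses. This note records the statistical model behind each
stage, the defaults and why they are set where they are, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Catalog construction

Assembled transcripts enter a three-predicate filter: (1) the transcript
locus must overlap a known lincRNA locus by at least 1 bp (strand-agnostic
interval intersection — "overlap" is not strand-qualified at this step);
(2) length ≥ 200 nt (the defining lower bound of a long non-coding RNA);
(3) the noncoding-potential score, when present, must be ≥ 0.5. Scores
near 1 indicate confident noncoding classification, so score-below-0.5
means "shows coding potential" and the transcript is removed; a missing
score keeps the transcript with a warning rather than silently discarding
data. All boundaries are inclusive by a literal reading of the
inequalities: length exactly 200 is kept, score exactly 0.5 is kept. The
three predicates are independent, so the filter is order-invariant (tested
by permuting the application order).

Isoforms mapping to one locus are collapsed by the arithmetic mean of
coverage and per-sample expression. Detection then uses a calling rate:
a locus counts as expressed in a sample at FPKM ≥ 0.3 (a detectability
threshold above background for this unit), and loci expressed in ≥ 20% of
samples are retained. The calling rate is computed on collapsed per-locus
values; computing it per transcript before collapsing is the plausible
alternative and would be slightly stricter.

## Discovery-stage differential expression

The discovery cohort is pair-matched (tumor t_i, adjacent normal n_i),
i = 1..N, measured in FPKM. Per feature:

* **Fold change**: log2((mean t + ε) / (mean n + ε)) with pseudocount
  ε = 0.1 (configurable). The pseudocount keeps sparsely expressed
  lincRNAs from producing infinite ratios; 0.1 sits well below the 0.3
  detection threshold so it never dominates a detected signal.
* **Test**: Wilcoxon signed-rank on the paired differences d_i = t_i − n_i.
  Zero differences are dropped before ranking, absolute differences are
  mid-ranked, and the reported statistic is the signed standardized value
  z = Σ sgn(d_i) r_i / sqrt(Σ r_i²), which is N(0,1) under the exchange
  null for moderate N. P-values are exact (full sign-flip null) for ≤ 25
  nonzero tie-free differences, otherwise normal with continuity
  correction. The standard paired nonparametric test is used because the
  design is pair-matched; a rank-sum variant that ignores pairing would
  discard the cohort's main strength.
* **Multiplicity**: Benjamini–Hochberg step-up across features.

**Permutation FDR.** On top of the per-feature tests the pipeline
estimates, for a threshold d on |z|, the false discovery rate

    fdr(d) = E_perm[ #{j : |z_j^perm| ≥ d} ] / #{j : |z_j^obs| ≥ d},

with the expectation approximated by B label permutations (default
B = 1000). A permutation exchanges the tumor/adjacent labels within each
pair independently with probability ½ — equivalently it flips the sign of
each pair's difference vector — which preserves the paired structure the
test assumes; shuffling whole columns would break pairing and inflate the
permutation variance. The same sign flips apply to every feature within
one permutation, preserving inter-feature correlation in the null counts.

The raw curve is a ratio of counts and can be locally non-monotone. It is
monotonized **conservatively**: the reported fdr(d) is the running maximum
of the capped raw values from the largest threshold downward, which makes
the curve non-increasing in d without letting a noise dip at an extreme
threshold leak a small FDR to lenient thresholds. (A running *minimum* in
that direction — superficially the symmetric choice — propagates the
near-zero FDR attained at the most extreme d to every smaller d, so the
rule "smallest d with fdr(d) < 1%" would degenerate to selecting every
feature; simulation shows a realized false-discovery proportion near 90%
under that variant versus ≈ 1% under the conservative one.)

**Selection rule**: a feature is called DE iff |log2FC| ≥ 1 (two-fold),
BH-adjusted p < 0.01, and |z| ≥ d*, where d* is the smallest grid point
with estimated FDR < 1%. On simulated cohorts at the study's scale
(85 pairs, 500 features, 10% planted strong DE), the realized
false-discovery proportion under this rule averages ≈ 1%.

## Replication-stage testing

The replication cohort is sequenced to integer counts, so testing moves to
a negative-binomial GLM with variance μ + φμ². The path is a compact,
auditable emulation of the standard count-DE workflow:

* **Normalization**: trimmed mean of M-values. Per sample against a
  reference column (the sample whose library-scaled upper quartile is
  closest to the cohort mean), per-gene log2 ratios M and average
  log-intensities A are computed over genes nonzero in both samples,
  doubly trimmed (30% of M and 5% of A from each tail, by mid-rank), and
  averaged with inverse-asymptotic-variance weights
  w = 1 / [(N−x)/(Nx) + (N_r−r)/(N_r r)]; the factor is 2 to that mean,
  and factors are rescaled to geometric mean 1. The implementation agrees
  with the Bioconductor reference implementation to 1e-6 relative (tested
  via Rscript) and with a plain-loop transcription of the definition to
  1e-10.
* **Dispersion**: per-feature method-of-moments estimate
  φ̂ = Σ[(y−μ̂)² − μ̂] / Σ μ̂² with group-specific effective-library means,
  floored at 0 and shrunk toward the cohort median with weight 0.3. This
  is a deliberately simple stand-in for empirical-Bayes shrinkage: the
  median anchors unstable per-feature estimates, and 0.3 keeps genuine
  dispersion differences visible. At Poisson-simulated large counts the
  common estimate stays below 0.05; planted φ = 0.4 is recovered within
  [0.25, 0.6] at 50 samples.
* **Test**: per feature, log-link NB GLM (IRLS at fixed dispersion) of
  counts on tissue type plus covariates — age standardized, race and
  sequencing batch one-hot — with log(library size × TMM factor) offsets;
  significance from a 1-df likelihood-ratio chi-square for the tissue
  term, BH across features. The coefficient divided by ln 2 is the
  replication log2FC. In the φ→0 limit the statistic agrees with a
  Poisson GLM LRT.

**Replication criterion**: a discovery hit replicates iff |log2FC| ≥ 1
and P < 0.05 in the paired tumor-vs-adjacent comparison, with direction
concordant with discovery; the same rule against healthy-normal tissue is
reported separately, and a relaxed 1.5-fold gate (|log2FC| ≥ 0.585) is
available. The packaged 37-row two-stage table reproduces the published
counts under this rule: 37/37 rows pass the paired criterion and 30/37
(81%) the tumor-vs-normal one. Whether the printed replication P values
were raw or FDR-adjusted is not recoverable from the table itself; both
gates are exposed (`p_raw`, `p_fdr`) and the fixture check uses the values
as printed.

## TF–lincRNA network

A lincRNA is bound by a TF when any of the TF's ChIP-seq peaks overlaps,
by ≥ 1 bp, the window from 2 kb upstream of the transcription start site
to the transcription end site — [start−2000, end) on '+', [start, end+2000)
on '−', clipped at zero. Peaks are unstranded; the window is
strand-aware. No minimum overlap fraction is imposed (nothing in the rule
suggests one). Multiple peaks collapse to a single edge; degree counts
distinct partners. Nodes with no edges do not enter the network. TFs of
degree ≥ 5 are "key TFs"; a separate expression screen flags TFs at
|log2FC| ≥ 0.585 with BH p < 0.01.

## Neighboring-gene analysis

Each lincRNA pairs with the protein-coding gene at the smallest boundary
gap on its chromosome (0 when overlapping). Distance is strand-ignored
boundary-to-boundary — "closest physical distance" without further
qualification; TSS-to-TSS is the untaken alternative. Equidistant ties
resolve deterministically to the lower-coordinate gene and are flagged.

Orientation: same strand → head-to-tail (H2T). Opposite strands → the
pair is divergent (H2H) when the minus-strand feature's TSS lies at or
left of the plus-strand feature's TSS, convergent (T2T) otherwise; the
same 5′-end rule covers overlapping features (flagged). Note the class is
invariant under reflection of the locus (mirror coordinates + flip both
strands) and under swapping which feature is called the lincRNA, but a
strand flip alone exchanges H2H and T2T — that is geometry, not a bug.

Coordinated expression change is an OLS fit of lincRNA log2FC on partner
log2FC (slope, r², slope-test p), compared against two nulls: for each
lincRNA one uniformly drawn coding gene > 1 Mb away or on another
chromosome, and 1000 uniformly random lincRNA–gene pairs. H2H
over-representation among the DE pairs uses a one-sided binomial tail
with the baseline proportion p₀ taken from the full catalog's
lincRNA–nearest-gene orientation distribution (the natural reference when
no external genome-wide figure is supplied).

## Function inference

Spearman correlations between a lincRNA and all coding genes are
thresholded at |ρ| ≥ 0.4, both signs retained. The cutoff is checked
against a null of 1000 randomly shuffled lincRNA/gene pairings: when the
null's 0.5%/99.5% quantiles exceed 0.4 in magnitude the effective
threshold is raised to stay supra-null (at 85 samples the i.i.d. null's
extreme quantiles sit below 0.4, so the default binds). The co-expressed
set then feeds an upper-tail hypergeometric test against user-supplied
gene sets (GMT), BH-adjusted across sets, significant at adjusted
p ≤ 0.05. This is the standard open in-process equivalent of web-service
annotation enrichment, and is labeled as such in outputs. The universe
defaults to the coding genes that passed expression filtering —
unexpressed genes cannot be co-expressed, and including them would
inflate every enrichment. Co-expression is computed over all samples by
default; tumor-only or adjacent-only is a parameter.

## Clinical association

Patients split at the median expression of a lincRNA, ties to the low
group (a fixed rule keeps splits deterministic; medians are reported per
group). Survival is summarized by Kaplan–Meier product-limit curves,
compared by the 1-df log-rank test, and the high-vs-low hazard ratio comes
from a univariate Cox proportional-hazards fit with a Wald 95% CI
(lifelines; Efron tie handling — simulated times are continuous so ties
are almost surely absent and Efron = Breslow there). A survival "hit" is
log-rank p < 0.05; the HR Wald p is also emitted since either convention
is defensible. Monotone-likelihood cases (all events in one group) report
an infinite or zero HR with a flag rather than a spurious finite estimate.

Subtype analysis contrasts ER+ tumors against ER− tumors and against
normal tissue by unpaired Wilcoxon rank-sum with BH within each contrast;
"ER+-specific" requires both contrasts to pass |log2FC| ≥ 1 and adjusted
p < 0.05. This operationalizes "specifically high in ER+" as a testable
conjunction; no formula-level reference exists for it.

## Synthetic data: what it emulates, what it does not

The generators produce every input the pipeline consumes, with truth
recorded (`SimulationTruth`), so each downstream stage has a recoverable
target:

* **Annotation**: each lincRNA sits in its own 3-Mb block with one partner
  gene at a log-uniform gap (200 bp–100 kb) in a requested orientation;
  orientation counts follow the requested mix exactly
  (largest-remainder apportionment); decoy coding genes are ≥ 1 Mb from
  every lincRNA. The designated partner is therefore provably the nearest
  coding gene — a deliberately clean geometry with none of the nested or
  overlapping gene structure of a real genome.
* **FPKM cohorts**: log-normal baselines — lincRNAs LN(log 2, 1.2), coding
  genes LN(log 20, 1.0) — capture "low and sparse" lincRNA expression
  qualitatively; no distributional claim is made about the real cohorts.
  The tumor sample of a pair multiplies its baseline by 2^log2FC for
  planted features; per-sample log-normal noise (σ = 0.8) is shared
  within a designated neighbor pair through a latent factor weighted so
  the log-scale correlation equals the planted ρ (Spearman ≈ Pearson on
  this scale). Dropout zeroes lincRNA entries with a set probability.
  Real FPKM data additionally carry batch structure, length biases and
  tumor purity variation, none of which are modeled — passing tests show
  the estimators recover their own generative targets, not that they are
  robust to those artifacts.
* **Count cohorts**: gamma-Poisson (NB) counts with var = μ + φμ²,
  log-normal relative abundances, library sizes uniform in 0.5–2 M, and
  random batch/age/race labels for the covariate path.
* **Peaks**: one peak of width 200 bp centered 1 kb upstream of the target
  TSS per planted edge (± jitter), plus decoy peaks ≥ 10 kb outside every
  window.
* **Survival**: exponential event times, rate × HR in the high group,
  independent exponential censoring calibrated per group to the requested
  censored fraction. Real survival is rarely exponential; the generator
  exists to make the HR and log-rank calibration checkable, and the KM
  curves imply no parametric family.

All randomness flows from one integer seed through per-stage fixed
offsets; identical configurations are byte-identical on disk.

## Problem sizes used in the test and calibration suites

Calibration checks run at the cohort scale the estimators target where
that is cheap (85 pairs for the discovery stage, 50 pairs for the NB
recovery, n = 400 for HR recovery) and at 200 replicates for type-I-error
checks (log-rank and the paired test both land in [0.02, 0.09] at nominal
0.05). The permutation-FDR calibration uses 500 features, 10% planted DE
at |log2FC| = 3, B = 200 permutations and 50 simulation seeds; B is scaled
down from the analysis default of 1000, which leaves the FDR estimator's
Monte-Carlo noise at a few percent of its value without changing its
expectation. The end-to-end pipeline scenario (40 lincRNAs, 30 pairs)
is sized to exercise every stage in seconds.

## Known limitations

* The replication path is a compact emulation, not a reimplementation of
  any published count-DE package: no quasi-likelihood, no robust or
  trended dispersion, no exact small-sample tests. Per-feature GLM fits
  are sequential, which is fine at hundreds of features.
* The calling-rate filter is computed on collapsed loci; transcript-level
  calling is not implemented.
* `assign_edges` is an all-pairs scan — adequate for catalogs of
  hundreds of loci, quadratic beyond that (an interval index would be the
  next step).
* The shuffled-pair co-expression null samples with replacement when the
  pair space is small, which understates null spread for tiny catalogs
  (warned at run time).
* The H2H enrichment baseline p₀ is estimated from the input catalog, so
  with few lincRNAs it carries sampling noise the binomial test ignores.
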