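# Methods

## Scope and model

`hrdscar` implements the genomic-scar account of homologous recombination
deficiency (HRD) in tumors and the downstream discovery workflow for
HRD-associated prognostic transcripts.  A tumor that cannot repair
double-strand breaks by homologous recombination accumulates three
quantifiable lesion patterns in its allele-specific copy-number profile,
counted per sample from a table of segments `(chrom, start, end,
total_cn, minor_cn)`:

- **LOH** — number of loss-of-heterozygosity regions (minor allele absent,
  at least one copy retained) strictly longer than 15 Mb but shorter than
  the whole chromosome.  Contiguous minor-allele-absent segments are
  coalesced regardless of total copy number before the length test: LOH is
  an allelic state, not a copy state.
- **TAI** — number of allelic-imbalance regions (`total_cn ≠ 2·minor_cn`)
  that reach a subtelomere without crossing the centromere.  Each
  chromosome end is assessed independently, so a chromosome contributes at
  most 2; whole-chromosome imbalance crosses the centromere and
  contributes 0.
- **LST** — number of breakpoints (change in copy number or allelic
  content) between adjacent segments each spanning at least 10 Mb, after
  coalescing equal states and absorbing variants shorter than 3 Mb.
  Arms are processed independently, so a state change at the centromere is
  never a breakpoint; this mirrors the telomere/centromere logic of TAI
  and avoids artifacts from the assay dead zone around centromeres.

`HRD = LOH + TAI + LST`; a sample is classified HRD iff its score strictly
exceeds the cutoff (default 57, the minimum-log-rank-p optimum in the
ovarian-cancer setting this package emulates; `classify_hrd(57)` is
non-HRD).

Interpretation points the scar literature leaves open are fixed as
follows and are configurable: "longer than 15 Mb" is strict, "at least
10 Mb" is inclusive, "shorter than 3 Mb" is strict; homozygous deletions
(`total_cn = 0`) are not LOH; TAI has no minimum region length by
default.  Smoothing absorbs a short interloper into its longer flank
(left flank on ties), which conserves covered territory and makes the
filter order-independent and idempotent.

Coordinates are 0-based half-open in memory; SEG-style input files are
1-based inclusive and converted on read.  Uncovered gaps between segments
are tolerated and never bridged by default.  Integer allele-specific calls
are required: subclonal (fractional) copy numbers and purity/ploidy
correction are upstream concerns, out of scope here.

## Survival statistics

- Kaplan–Meier product-limit estimator (right-continuous step function).
- Two-group log-rank test: observed-minus-expected events over pooled
  distinct event times with the hypergeometric variance; the statistic
  `(O−E)²/V` is referred to a chi-square with 1 df.  This asymptotic
  p-value is what the package reports everywhere.  At very small n
  (≲ 10 subjects) the exact permutation distribution of the statistic is
  discrete with few atoms and the chi-square tail can deviate from it by
  0.1–0.4; the test suite quantifies this deliberately.  For cohorts of
  the size this package targets (hundreds of samples) the approximation
  is standard practice.
- Univariate Cox proportional-hazards fit: Newton–Raphson on the partial
  likelihood with Breslow tie handling, gradient tolerance 1e-8 on an
  internally standardized covariate (results reported on the input
  scale).  Monotone likelihood (complete separation) is detected as
  standardized-coefficient blow-up (|β·sd| > 8) and flagged
  `converged=False` instead of being returned silently.  Wald 95%
  intervals and p-values; simulation places their coverage at ~95% for
  n = 348 with a planted hazard ratio of 0.49.
- Optimal cutoff: candidates are midpoints between consecutive distinct
  observed scores, restricted so each side keeps ≥ 10% of samples; the
  candidate minimizing the log-rank p is returned (ties → smaller
  cutoff), with the full scan table retained.  No multiplicity correction
  is applied inside the scan — the reported minimum p is optimistic, as
  is inherent to minimum-p cutpoint selection; treat it as a selection
  device, not an inference.

## Expression screen

TPM normalization is the usual within-sample length-normalized abundance
(`rate = count/length`, scaled to 10⁶ per sample).  The DEG cascade runs,
in order: abundance (mean TPM > 1 in at least one of the contrasted
cohorts; configurable to "both"), variability (top 75% of genes by median
absolute deviation of log2(TPM+1), boundary ties kept), a per-gene
two-sided Wilcoxon rank-sum on log2(TPM+1) with Benjamini–Hochberg
adjustment over the tested genes (adj. p < .05), and fold change (mean
log2(TPM+1) difference exceeding log2 1.5).  Every gene records which
filter it failed first.  The rank-sum test is a deterministic,
assumption-light substitute for negative-binomial count modelling; with a
different per-gene test the cascade structure and thresholds are
unchanged but survivor counts will differ, so no attempt is made to
reproduce any particular count-model gene list gene for gene.  MAD and
fold change are computed on log2(TPM+1) for variance stabilization.

The extreme cohorts are the top and bottom `ceil(0.2·n)` samples by HRD
score (70 of 348), ties at the boundary broken by sample id.

Prognostic screening fits a univariate Cox model per DEG on continuous
log2(TPM+1) and keeps raw p < .05 — deliberately uncorrected, because the
penalized selection downstream is the gatekeeper.  Signature selection is
an L1-penalized Cox regression (scikit-survival's Coxnet path solver)
with the penalty assessed by 10-fold cross-validated partial-likelihood
deviance in the Verweij–van Houwelingen form (held-out contribution =
full-data partial log-likelihood minus training partial log-likelihood at
the training coefficients), computed with this package's own Breslow
evaluator.  Two penalty rules are provided: `"min"` (deviance minimum)
and the default `"1se"` (strongest penalty within one standard error of
the minimum).  The default is the parsimony rule: in simulations with one
strongly prognostic gene among 16 nulls at n = 348, the 1se rule selects
exactly the signal gene essentially always, while the deviance minimum
drags in a median of ~4 noise genes — the familiar lambda_min
overselection.  Path points where a fold's fit truncates or blows up
toward zero penalty (near-separation) are treated as missing and excluded
from the comparison.  Risk stratification splits the signature's linear
predictor at the cohort median (ties to the low-risk group) and reports
the high-vs-low log-rank test and Cox hazard ratio.

## Synthetic cohorts

The generator exists so that every stage can be validated against known
truth without any data download.  Its central property is that planted
scar counts are exact *by construction*, never by running the scorer:

- events occupy distinct chromosome arms of a toy genome (22 chromosomes
  of 200 Mb, centromere at 95–100 Mb) on a diploid heterozygous 2/1
  background;
- an LOH event is an interstitial 16–20 Mb minor-allele-absent region
  flanked by 4–8 Mb buffers of a third state (3/1): buffers are below the
  10 Mb LST bound, so none of its breakpoints qualify, and a ≥10 Mb
  balanced margin keeps both telomeres clean;
- a TAI event is a telomere-anchored 5–9 Mb 3/1 region: imbalanced,
  anchor within its arm, too short for LST, minor allele retained;
- LST transitions are chains of alternating balanced blocks (2/1 | 4/2),
  each ≥ 10.5 Mb, tiling an arm: balanced everywhere, so LOH and TAI are
  untouched; a chain of c+1 blocks contributes exactly c breakpoints.
  Up to 6 chains per arm are packed when large scores are requested.

Cohort survival is exponential with hazard
`baseline · hr^{HRD} · exp(Σ β_g z_g)` (defaults: baseline 0.03/month,
censoring 0.01/month, HR 0.49 — the HRD-vs-non-HRD contrast this package
emulates), where `z_g` is the realized standardized log2(TPM+1) of each
planted prognostic gene, so planted genes are predictive on exactly the
scale the screen tests.  Exponential rather than Weibull time keeps the
proportional-hazards assumption exactly true — the assumption every
downstream fit makes.

Expression counts are negative binomial (dispersion 0.15, log-uniform
base means 5–2000, log-normal size factors, gene lengths log-uniform
0.5–50 kb) with planted log2 effects applied between the HRD and non-HRD
groups.

Cohort HRD scores are drawn from well-separated status-conditional
distributions: non-HRD at `54 − Poisson(4)`, HRD at `60 + Poisson(4)`
(clipped to [0, 90]), leaving a dead zone around the threshold 57.  The
Poisson tails concentrate each group adjacent to the gap, which is what
makes the planted threshold identifiable by a minimum-p scan: splits
nearly equivalent to the true one then sit within a few score units of
57, and the scan recovers the threshold within ±5 in ≳95% of replicates.
With diffuse (e.g. uniform) score distributions the min-p scan is far
noisier — a real caveat for applying minimum-p cutpoints to flat score
distributions, documented here because the simulation makes it visible.
A planted total is split deterministically as TAI = min(12, 0.2·total),
LOH = min(12, 0.25·total), LST = remainder, respecting arm capacity.

What the generator does **not** emulate: SNP-array noise and dead zones,
subclonality, tumor purity, genuinely continuous scar-score distributions,
correlated gene-gene expression structure, or batch effects.  Passing
tests therefore demonstrate correctness of the counting rules and
estimators under clean conditions, not robustness to real-data artifacts.

## Numerical and degenerate-input choices

- Merging coalesces equal states separated by at most `gap_tolerance`
  (default 0 = exact adjacency); smoothing keeps a lone short segment
  with no neighbors.
- Sub-seeds for replicate simulations are drawn below 2³¹ from a seeded
  generator; identical seeds give byte-identical cohort bundles.
- Problem sizes used by the validation suite and the acceptance script —
  1000 profiles for scar exactness, 200 replicates for Cox recovery, 100
  for cutoff recovery, 50 for end-to-end signature recovery — were chosen
  to estimate each rate to within a few percent while keeping a full run
  in minutes on a single core.
- Constant genes are skipped (with a warning) by the Cox screen; constant
  covariates, empty matrices, all-equal scores and overlapping cohorts
  raise errors rather than degenerate silently.

## Known limitations

- The chi-square log-rank p is asymptotic; see above for small-n behavior.
- Minimum-p cutoffs are optimistic and should be validated externally.
- The per-gene DE test ignores count overdispersion structure; genes with
  very low counts are handled by the abundance filter, not by the test.
- TPM is compositional: a few strongly changed genes shift all other
  genes' TPM between groups.  The fold-change threshold guards the
  cascade against small compositional shifts but cannot remove the
  effect.
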