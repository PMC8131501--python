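# hrdscar

Genomic-scar scoring of homologous recombination deficiency (HRD) and the
downstream screen for HRD-associated prognostic transcripts, as used in
survival studies of high-grade serous ovarian cancer.

Tumors that cannot repair DNA double-strand breaks by homologous
recombination respond preferentially to PARP inhibitors and platinum, but
they leave tell-tale scars in their allele-specific copy-number profile.
`hrdscar` counts the three canonical scars from a segment table
`(sample, chrom, start, end, total_cn, minor_cn)`:

- **LOH** — loss-of-heterozygosity regions (minor allele lost, ≥ 1 copy
  retained) longer than 15 Mb but shorter than a whole chromosome;
- **TAI** — allelic-imbalance regions reaching a subtelomere without
  crossing the centromere;
- **LST** — large-scale state transitions: breakpoints between adjacent
  ≥ 10 Mb segments after smoothing away sub-3-Mb variants,

and defines **HRD = LOH + TAI + LST**, with HRD status assigned when the
score strictly exceeds a cutoff (57 by default, the minimum-log-rank-p
optimum in the ovarian-cancer setting; a score of exactly 57 is non-HRD).

Around the score, the package provides the full discovery workflow:

1. **Survival statistics** — Kaplan–Meier curves, the two-group log-rank
   test, univariate Cox regression (Breslow ties, Newton–Raphson), and
   the minimum-p-value cutoff scan that dichotomizes a score where the
   log-rank p is smallest.
2. **Expression screen** — TPM normalization; contrast of the top vs
   bottom 20% of samples by HRD score; a DEG cascade (mean TPM > 1,
   top-75% MAD, BH-adjusted rank-sum p < .05, fold change > 1.5);
   univariate Cox screening of the DEGs; lasso–Cox signature selection
   with 10-fold cross-validated deviance; median-split risk
   stratification.
3. **Synthetic cohorts** — a generator that plants exact scar counts by
   construction geometry, exponential survival with a chosen hazard
   ratio, and negative-binomial expression with planted differential /
   prognostic genes, so every stage can be validated against known truth
   without downloading anything.

See `docs/methods.md` for the precise definitions, tie-breaks and design
choices.

## Worked example

Simulate a 348-sample cohort with one HRD-upregulated protective gene
planted among 500, then run the full pipeline:

```python
import hrdscar as h
from hrdscar.pipeline import PipelineConfig, run_full_pipeline

bundle = h.simulate_cohort(n_samples=348, seed=7, n_genes=500,
                           de_spec={0: 2.0},          # +2 log2 in HRD tumors
                           prognostic_spec={0: -0.9}) # protective per SD
paths = h.write_bundle(bundle, "demo")
cfg = PipelineConfig(segments=str(paths["segments"]), genome=str(paths["genome"]),
                     clinical=str(paths["clinical"]), counts=str(paths["counts"]),
                     lengths=str(paths["lengths"]), outdir="demo_out", seed=7)
summary = run_full_pipeline(cfg)
```

The summary this prints (abridged):

```
score:                 n_samples 348, mean HRD 57.03
cutoff:                57.5 (min-p scan, p = 6.5e-40), 174 HRD samples
extremes:              70 high vs 70 low
differential_expression: 1 DEG (1 up in the HRD group)
cox_screen:            1 candidate: G0001
signature_selection:   signature [G0001], coefficient -0.434
risk_stratification:   HR 6.01 (95% CI 4.36–8.27), log-rank p = 1.3e-33
```

Reading it: the scar scorer recovers the planted score distribution
(mean ≈ 57); the min-p scan finds the planted 57 threshold (candidates
are midpoints of observed scores, hence 57.5); the extreme-cohort
contrast isolates the single planted DEG among 500 genes; the Cox screen
and the lasso keep exactly that gene; and splitting the cohort at the
median risk score separates survival strongly — the high-risk group
(low expression of the protective gene) dies about six times faster.

The same stages are available from the shell:

```sh
hrdscar simulate --n 348 --seed 7 --outdir demo/
hrdscar score   --segments demo/segments.tsv --genome demo/genome.tsv -o scores.tsv
hrdscar cutoff  --scores scores.tsv --clinical demo/clinical.tsv
hrdscar run     --segments demo/segments.tsv --genome demo/genome.tsv \
                --clinical demo/clinical.tsv --counts demo/counts.tsv \
                --lengths demo/lengths.tsv --cutoff 57 --outdir demo_out/
```

## Input formats

All inputs are plain TSV: a genome table (`chrom length cen_start
cen_end`), SEG-like segments (`sample chrom start end total_cn minor_cn`,
1-based inclusive), clinical follow-up (`sample time event`), a gene ×
sample count matrix and a gene-length table.  `hrdscar simulate` writes a
complete, consistent bundle plus the generating truth as JSON.
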