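# bwtpred

Analysis toolkit for bilateral Wilms tumor (BWT) predisposition from
multi-tissue molecular data. It implements, as a tested and reusable
pipeline:

- **11p15.5 imprinting classification** — mean methylation β over the
  *H19*/ICR1 (chr11:2,019,974–2,024,738) and *KCNQ1OT1*/ICR2
  (chr11:2,721,228–2,722,228, GRCh38) windows, thresholded at β 0.7 / 0.3
  into ROI / LOI / LOH, with a cnLOH override from sequencing-derived
  segments.
- **Low-level mosaic hypermethylation detection** — blood H19/ICR1 β
  compared against a healthy-control cohort cutoff (mean + 2 sample SD),
  plus a closed-form mosaic-fraction estimate from a linear purity/mosaic
  mixture model.
- **Germline variant triage** — an ordered decision cascade (gene panel →
  indel/nonsense → ClinVar assertion → PROVEAN/PolyPhen-2 → tumor VAF
  enrichment via a one-sided exact test with an effect-size floor).
- **Paired-tumor concordance** — shared coding/noncoding somatic variants,
  binned copy-number profile similarity, 11p cnLOH breakpoint comparison,
  and a categorical embryonic-origin call (independent / shared early
  clone / suspected same-kidney multifocal).
- **Integrated per-patient reports** — predisposition mode
  (GERMLINE_GENETIC / POSTZYGOTIC_MOSAIC_LOI / UNCLASSIFIED) with a
  mosaicism evidence tier (tumor → tumor+kidney → tumor+kidney+blood), and
  cohort statistics (status fractions, germline×ICR chi-square association,
  group β comparisons, purity–β correlation).
- **Synthetic cohort generator** — blood/kidney/tumor trios with planted
  modes, mosaic fractions, purity mixing, probe noise, planted
  shared/private noncoding variants and triage-compatible germline
  annotations, plus a ground-truth file the pipeline never reads.

Two reference tables of paired-tumor variant sharing are packaged as
fixtures (`bwtpred.fixtures`) and validated by the test suite.

## Conventions

- All tabular exchange formats are tab-delimited UTF-8 with `.` decimals.
- Genomic coordinates are **1-based, end-inclusive** everywhere, including
  the BED-like CNV segment tables.
- Missing tumor purity is an **empty field**, never 0 (0 is a legal purity).
- β exactly equal to a classification threshold falls in no category and
  yields INDETERMINATE with a warning (the thresholds are strict).

## CLI

```sh
bwtpred simulate --n-patients 20 --seed 7 --out cohort/
bwtpred classify-icr --beta-matrix cohort/beta_matrix.tsv \
    --samples cohort/samples.tsv --cnv cohort/cnv_segments.tsv --out calls.tsv
bwtpred gom --controls controls.tsv --cases cases.tsv --out gom.tsv
bwtpred triage --variants cohort/germline_variants.tsv --out verdicts.tsv
bwtpred pairs --samples cohort/samples.tsv --coding cohort/somatic_coding.tsv \
    --noncoding cohort/somatic_noncoding.tsv --cnv cohort/cnv_segments.tsv \
    --calls calls.tsv --out pairs.tsv
bwtpred report --calls calls.tsv --triage verdicts.tsv \
    --controls controls.tsv --out report.json
```

Thresholds, region coordinates, mixture-model baselines and pair-flagging
cutoffs can be overridden with a YAML file passed via `--config`
(see `bwtpred.config.PipelineConfig`).

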