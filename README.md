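# sevmir

Analysis toolkit for small-extracellular-vesicle (sEV) miRNA secretion in
stress-induced premature senescence (SIPS vs. quiescent fibroblasts):

* **io** — typed readers/writers for vesicular qPCR Ct matrices (with
  spike-in rows and an explicit not-detected encoding), intracellular
  small-RNA-seq count matrices, sample sheets and NTA particle tables —
  all plain TSV/CSV.
* **qc** — spike-in robustness (Ct range < 1 cycle across samples) and
  detection-category summaries (<31 / 31–35 / 35–38 / >38-ND bins,
  donor-overlap counts).
* **normalize** — per-cell Ct normalization (`Ct + log2(cells/ref)`),
  global-mean (mean-centering restricted) Ct normalization, and TPM with
  the "≥ 5 TPM in all samples of at least one donor" filter.
* **differential** — donor-blocked least-squares models per miRNA with
  empirical-Bayes variance moderation (method-of-moments scaled-F prior),
  Benjamini-Hochberg FDR and volcano classification.
* **secretion** — the core scoring: co-measurement filter (quartile /
  TPM-zero / completeness steps), Ct→arbitrary-units transform (Ct 40 ↦
  10 AU, base 2), per-condition rank-difference and vesicular-over-
  intracellular ratio scores, their SIPS-vs-Q shifts, dual 25/75-percentile
  classification into selectively secreted / retained / neutral, and
  cross-method concordance (Spearman, top-k overlaps).
* **evmetrics** — NTA size histograms, median particle size (X50),
  particles-per-cell fold changes, apoptosis-percentage arithmetic.
* **simulate** — a synthetic-data generator with the study's structure
  (3 donors × {Q, SIPS} × {D7, D21}, ~10× lower SIPS cell input, 4×
  vesicles per cell in SIPS, planted DE / composition / packaging sets,
  Ct censoring at 40, negative-binomial counts) plus ground-truth tables
  and a recovery report, so the whole pipeline runs with no downloads.

## CLI

```sh
sevmir simulate --seed 1 --outdir data/            # synthetic dataset
sevmir qc --ct data/ct.tsv --samples data/samples.tsv --out out/qc
sevmir normalize --scheme mcr --matrix data/ct.tsv --samples data/samples.tsv --out out/mcr.tsv
sevmir diff --matrix data/ct.tsv --scheme per_cell --samples data/samples.tsv --day D21 --out out/de.tsv
sevmir correlate --ct data/ct.tsv --counts data/counts.tsv --samples data/samples.tsv --out out/scores.tsv
sevmir evmetrics --particles data/particles.tsv --samples data/samples.tsv --out out/ev
sevmir report --indir data/ --outdir out/report    # full chain + summary.json
```

`report` emits every result table (QC, three normalizations × two days of
differential tests, secretion scores with labels, EV metrics, planted-truth
confusion when `truth.tsv` is present) and a deterministic `summary.json`.

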