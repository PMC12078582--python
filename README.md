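# tblsuite

Quantifying structural-variant-associated genomic instability in cancer
with the **tumor break load (TBL)** — the per-sample count of unbalanced
somatic chromosomal breaks — and the analyses that give the measure its
biological and clinical meaning. The package is aimed at cancer
genomicists who have segmented copy-number profiles (SEG), SV call sets
(BEDPE), mutation tables (MAF-like), expression counts and clinical
tables, and want to compute and interpret SV burden alongside the tumor
mutational burden (TMB) and fraction genome altered (FGA).

## The measure and the analyses around it

**TBL from segments.** Every boundary between adjacent copy-number
segments of a chromosome is a candidate break. A candidate is retained
when its *smallest adjacent segment size* (SAS, the smaller probe count
of the two flanking segments) is at least 20 probes **and** its *break
size* (BrS, the absolute change in log2 segment mean, |Δseg.mean|) is at
least 0.135, and the boundary is not seen at any position of a matched
normal panel (likely germline variants or platform artifacts). TBL is
the number of retained breaks. From SV calls, TBL is instead the number
of breakpoints of copy-number-changing events (DEL, DUP; two breakpoints
per event by default), with balanced INS/INV/TRA excluded. FGA is the
fraction of profiled genome length at |log2 ratio| ≥ 0.2; TMB counts
non-silent small variants.

Downstream stages:

* **landscape** — pan-cancer variability (scaled standardized IQR of the
  pooled ranks per cancer type), Pearson R² between measures, and
  Mann-Whitney stage/MSI associations;
* **cibra** — transcriptome impact of a measure: samples are ranked and
  the first/last quartiles labelled HIGH/LOW; 10 random subsamples of
  10 HIGH vs 10 LOW samples are scored by the fraction of genes
  differentially expressed (a pluggable negative-binomial Wald DE
  contract), and tested (Mann-Whitney) against a reference distribution
  of 1000 random 10-vs-10 permutations of the cohort;
* **enrichment** — genes ranked by `score = sgn(mean fc) ·
  −log10(mean p_adj)` over subsamples, then preranked GSEA with a
  weighted Kolmogorov–Smirnov running sum and a gene-permutation null;
* **association** — per gene (SNV, SV) and per chromosome arm
  (gain/loss) Mann-Whitney screens of altered vs wild-type samples
  against each measure, with ≥10/≥10 group filters, MSI exclusion,
  local-burden correction (in-gene SNVs subtracted from TMB, in-gene SV
  breakpoints from TBL), and per-screen FDR control;
* **survival** — dichotomization at the Youden-index threshold of the
  ROC for the endpoint's event, Kaplan–Meier/log-rank, and multivariate
  Cox proportional-hazards models adjusted for age, sex and stage.

Everything is driven and validated by a **synthetic cohort generator**
(`tblsuite.synthetic_data`) that plants somatic events, sub-threshold
artifacts, panel-matched germline breaks, MSI-linked SNV excess,
burden-linked expression effects and proportional-hazards survival — 
with the full ground truth exposed.

## Worked example

```python
from tblsuite import SimulationConfig, simulate_cohort, compute_measure_table
from tblsuite import cibra, survival

cfg = SimulationConfig(seed=11, n_samples=400, driver_genes=("G0001",))
cohort = simulate_cohort(cfg)
table = compute_measure_table(cohort.tumor_seg, cohort.normal_seg,
                              cohort.sv, cohort.mutations, cohort.clinical)
print(table[["sample_id", "tbl", "tbl_sv", "fga", "tmb"]].head(3).to_string(index=False))

import numpy as np
measure = table.set_index("sample_id")["tbl"].astype(float)
res = cibra.cibra_analysis(cohort.counts, measure, n_perm=1000, seed=12)
print(f"impact p = {res.p:.3g}, "
      f"median proportion score = {np.median(res.score_values):.3f}")

row = survival.survival_analysis(table, cohort.clinical, "tbl", "dfs").iloc[0]
print(f"DFS: n = {row['n']}, Youden threshold = {row['threshold']:.1f}, "
      f"HR = {row['hr']:.2f} [{row['ci_low']:.2f}-{row['ci_high']:.2f}], "
      f"log-rank p = {row['logrank_p']:.4f}")
```

prints

```
sample_id  tbl  tbl_sv   fga  tmb
SIM_T0001   22      24 0.592  323
SIM_T0002   42      46 0.725    2
SIM_T0003   71      74 0.616   88
impact p = 1.79e-48, median proportion score = 0.176
DFS: n = 203, Youden threshold = 51.5, HR = 1.88 [1.33-2.67], log-rank p = 0.0004
```

Reading the output: each sample gets its break load from segments
(`tbl`) and from SV calls (`tbl_sv`, two breakpoints per DEL/DUP), FGA
and TMB — note how weakly the three co-vary (`SIM_T0002` carries 42
breaks but only 2 SNVs): they capture different facets of instability,
which is the point of measuring SV burden separately. The impact
analysis finds that
17.6% of genes separate the TBL-high from the TBL-low quartile — far
outside the permutation reference (Mann-Whitney p ≈ 2e-48), matching
the planted 20% DE fraction after test power. The survival stage
dichotomizes the localized MSS untreated cohort at TBL ≥ 51.5 and
estimates a hazard ratio of 1.88 (the generator's true high-group HR
is 2.0).

The same pipeline is scriptable from the shell:

```sh
tblsuite simulate --config cfg.yaml --out cohort/
tblsuite measures --seg cohort/tumor.seg --normals cohort/normals.seg \
    --sv cohort/svs.bedpe --maf cohort/mutations.tsv --out measures.tsv
tblsuite cibra --counts cohort/counts.tsv --measures measures.tsv --out cibra/
tblsuite survival --measures measures.tsv --clinical cohort/clinical.tsv \
    --endpoint dfs --out survival/
```

## Layout

```
src/tblsuite/
  io_formats.py      SEG / BEDPE / MAF-like / counts / clinical / GMT
  synthetic_data.py  cohort generator with planted ground truth
  measures.py        TBL (segments & SV), FGA, TMB
  landscape.py       variability, correlations, stage/MSI tests
  cibra.py           quartile groups, DE contract, impact score
  enrichment.py      signed ranking score, preranked GSEA
  association.py     alteration screens with burden correction
  survival.py        Youden threshold, KM/log-rank, Cox PH
  cli.py             `tblsuite` console entry points
```
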