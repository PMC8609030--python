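# coexdyn

Longitudinal differential gene co-expression analysis for matched
case/control cohorts.

`coexdyn` asks a question that single-time-point transcriptomics cannot:
do the *relationships* between genes — not just their expression levels —
change in the months before a clinical event?  It was built for prospective
blood-transcriptome studies of type 1 diabetes progression, where children
at genetic risk are sampled repeatedly before diagnosis, but applies to any
design with repeated expression measurements, a case/control split, and a
per-subject time axis anchored at an event.

## The method

1. **Windowing and matching.**  Samples are grouped into 10-day analysis
   windows spanning the 600 days before diagnosis.  At each window every
   case subject contributes its sample drawn closest to the window day
   (only if within 100 days), and each case sample is matched to same-sex,
   age-nearest control samples.  Two independent control sets are drawn and
   every statistic is averaged over them.
2. **Reference network.**  A weighted co-expression network is built once,
   from case samples ~180 days before diagnosis: soft-threshold adjacency
   `a_ij = |cor(x_i, x_j)|^β` (β = 12 by the scale-free topology
   criterion), topological overlap

   `t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, `l_ij = Σ_u a_iu a_uj`,

   average-linkage clustering of `1 − TOM`, and a height cut plus
   minimum-size filter with eigengene merging.  The resulting module
   partition is held fixed for every other time point.
3. **Differential connectivity.**  Per window, module and sex stratum,
   module connectivity `MC = Σ_{i<j} t_ij` is recomputed from group-specific
   correlations (at β = 8) and compared as **modular differential
   connectivity** `MDC = MC_cases / MC_controls`.  Significance of gain
   (MDC > 1) and loss (MDC < 1) is the empirical tail probability under
   case/control label permutation, with Benjamini–Hochberg adjustment
   across windows.  Per gene, the within-module connectivity
   `GC_i = Σ_{u≠i} a_ui` gives `δH_i = GC_cases − GC_controls` and
   `GDC_i = GC_cases / GC_controls`; genes are ranked by δH within each sex
   and the ranks summed into the final differentially-connected-gene list.
4. **Module expression.**  The module eigengene (first principal component)
   is computed once on the reference window and *projected* through that
   fixed rotation at every other window, so eigengene values are comparable
   across time; case/control differences use Welch t-tests, per-probe
   differential expression uses Bonferroni control (0.05 / n probes).
5. **Enrichment.**  Modules are tested for over-representation of supplied
   gene sets (GMT format) with one-sided hypergeometric tests and BH
   adjustment.

Because the motivating cohort data are access-restricted, the package
ships a first-class synthetic-cohort generator (`coexdyn.synthetic`) that
plants co-expression modules through a one-factor model — within-module
correlation `λ²/(λ²+σ²)` — with group- and time-dependent connectivity
shifts and sub-5% expression shifts, plus full ground truth, so the whole
pipeline is testable end to end.

## Worked example

```bash
coexdyn demo --seed 1 --outdir demo_out
# or: python -c "from coexdyn.pipeline import demo; demo(seed=1, out_dir='demo_out')"
```

The demo generates a cohort of 40 cases and 40 controls (200 genes), with
one planted module (`alpha`) whose within-module correlation doubles from
0.3 to 0.6 in case samples drawn 250–150 days before diagnosis, and a
time-constant control module (`beta`).  It then runs the full pipeline and
prints:

```
Top module/sex MDC peaks by |log MDC|:
   module sex  window_day   mdc  log_mdc  p_gain  q_gain
turquoise   M         210 105.2    4.656       0       0
turquoise   F         200 50.19    3.916       0       0
     blue   M         350 0.145   -1.931    0.99       1
     blue   F         340 6.851    1.924    0.02    0.61

Top 10 differentially connected genes, module turquoise:
       gene  delta_h_F  delta_h_M  gdc_F  gdc_M  rank_F  rank_M  final_rank
alpha_G0002      2.456      6.289  130.6  81.46       8       2          10
alpha_G0010      2.617      6.242  41.33  155.2       7       3          10
alpha_G0000      3.005      4.943  36.05   1595       3       9          12
...
```

Reading this: the detected `turquoise` module (which recovers the planted
`alpha` genes) shows a strong, permutation-significant gain of connectivity
(MDC ≈ 50–105, q < 0.05) peaking at 200–210 days before diagnosis — inside
the planted 150–250-day shift window — in both sexes, while the
time-constant `blue` module shows no BH-significant change.  The five
planted hub genes (`alpha_G0000`–`alpha_G0004`) surface at the top of the
differentially-connected-gene ranking.  All tables (QC report, window
assignments, module partition, MDC time course, eigengene/DME series,
differential expression, gene rankings, enrichment, run manifest) are
written as TSV/JSON under `demo_out/`.

The same pipeline runs on real data from an expression TSV + sample-sheet
TSV + GMT file through a YAML config (`coexdyn all --config cfg.yaml`), or
stage by stage (`coexdyn qc`, `coexdyn windows`, `coexdyn network`, ...).

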