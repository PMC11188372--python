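# toxregulon

Dose-response analysis of transcription-factor regulon dysregulation in liver
toxicogenomics studies.

Acute-exposure rodent studies (e.g. PFAS and PAH chemicals dosed over several
days, both sexes, a wide dose ladder) produce gene-level expression matrices
in which the earliest signs of an adverse outcome such as hepatic steatosis
appear as coordinated shifts in the target genes of specific transcription
factors — the molecular initiating events (MIEs) of an adverse outcome
pathway. `toxregulon` turns that analysis into a tested, reusable pipeline
for toxicologists and computational biologists:

- **Sample QC** on sequencing metrics (depth, alignment rates, probe
  coverage) with a strictly-below failure rule, plus replicate-outlier
  flagging by median inter-replicate Spearman correlation.
- **Normalization**: reads-per-million scaling and pseudo-count log2
  transform, `x -> log2(RPM + 1)`.
- **Transcriptome extrapolation**: principal-component regression trained on
  a reference compendium maps a measured sentinel gene panel (a targeted
  platform like TempO-Seq S1500+) to the whole transcriptome.
- **Differential expression** per (chemical, dose, sex) condition:
  `log2FC = mean(log2 treated) − mean(log2 control)` with n treated animals
  against the pooled same-sex vehicle controls, a one-way ANOVA (for two
  groups, F = t² of the pooled t-test), and Benjamini–Hochberg q-values
  adjusted across genes within each condition.
- **MIE regulon profiling**: TRRUST-dialect TF→target tables, human→rat
  symbol conversion, and per-MIE counts of dysregulated targets at the
  inclusive thresholds log2FC ≥ 0.6 (up) and ≤ −0.6 (down).
- **Response classification** per gene from top-dose fold changes:
  `consistent_up/down`, `sex_dependent` (opposite sign between sexes),
  `class_dependent` (opposite sign between PFAS and PAH), or `none`; plus
  dose-trend detection (consistent sign, top-dose |log2FC| ≥ 0.6, and fold
  change moving with dose) and concordance against weighted pathology gene
  signatures at q < 0.1.
- **A synthetic-data generator** that emulates the full study design
  (4 chemicals, 9 doses plus vehicle, both sexes, n = 5 treated vs n = 10
  controls per sex) with planted MIE-level, sex-specific and class-specific
  effects and an exact ground-truth table, so every stage is testable without
  any downloads.
- **Exports**: TSV tables throughout, SIF/GraphML networks with up/down node
  coloring classes, clustered heatmap matrices, and a JSON run manifest.

## Worked example

Simulate a two-chemical study (one PFAS, one PAH; three doses; 3 treated vs 4
control animals per sex) with an upregulation effect of max log2FC = 2 planted
on the PPARα regulon in the PFAS arm only, then profile MIE target
dysregulation at the PFAS top dose in males:

```python
import toxregulon as tr

edges = tr.read_regulatory_table("tests/data/demo/regulons.tsv")
edges, report = tr.map_symbols(edges, tr.read_symbol_map("tests/data/demo/mapping.tsv"))
mies = tr.read_mie_list("tests/data/demo/mies.tsv")

design = tr.StudyDesign(
    chemicals=[
        tr.Chemical("6:1 FTOH", "PFAS", (12, 111, 1000)),
        tr.Chemical("2,3-Benzofluorene", "PAH", (12, 111, 1000)),
    ],
    n_treated=3, n_control=4, n_genes=40,
)
effects = [tr.PlantedEffect(tf="Ppara", direction="up", max_log2fc=2.0, classes=("PFAS",))]
bundle = tr.simulate_study(design, edges, effects, noise_sd=0.4, seed=20240605)

fc = tr.build_fc_table(bundle.expression, bundle.metadata)
network = tr.build_mie_network(edges, mies, bundle.expression.genes)
profile = tr.profile_conditions(fc, network)
top = profile[(profile.chemical == "6:1 FTOH")
              & (profile.dose_mg_per_kg == 1000) & (profile.sex == "male")]
print(top[["mie", "n_up", "n_down", "n_total"]].to_string(index=False))
```

This prints:

```
   mie  n_up  n_down  n_total
 Ppara     8       0        8
 Hnf4a     1       0        1
   Ahr     0       1        1
 Nr3c1     0       0        0
Srebf1     0       1        1
  Esr1     0       0        0
```

All 8 mapped PPARα targets are counted as upregulated at the top dose (the
planted effect), while the other MIEs show only the background noise level —
the per-MIE count matrix is how competing MIE hypotheses are ranked.

The same analysis runs from the shell:

```bash
toxregulon run --config tests/data/demo/config.yaml --output-dir demo_out
```

which writes the fold-change table, the per-MIE profile (long format and the
MIE × chemical × sex × dose count table), response-pattern calls with dose
trends, signature concordance, SIF networks with node attributes, per-sex
clustered heatmap matrices, and `manifest.json`.

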