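# gutreg

Integrative regulatory-genomics analysis of how gut microbiota reshape
intestinal epithelial transcription through a host transcription factor —
packaged as a tested, reusable pipeline with a fully synthetic,
ground-truthed data generator.

## The scientific problem

Colonizing a germ-free (GF) animal with a microbiota (conventionalization,
CV) changes the transcription of hundreds of intestinal epithelial genes.
One proposed mechanism is that colonization *suppresses* the activity of a
nuclear-receptor transcription factor (an HNF4-family activator): genes the
TF activates lose expression upon colonization, the TF's genome-wide
binding is largely lost in CV, enhancer marks shift in the same direction
as nearby transcripts, and the resulting expression signature resembles
human inflammatory bowel disease (IBD).

Testing that model requires integrating five analyses, each of which this
package implements against explicit contracts:

1. **Differential expression on a 2×2 design** (genotype WT/Mut ×
   colonization GF/CV) with a documented negative-binomial two-group
   likelihood-ratio test (`gutreg.diffcount`) used for both gene and
   ChIP region counts.  Counts are modeled as NB(μ·f_s, α) with
   median-of-ratios size factors f_s, a method-of-moments dispersion α
   pooled across genes, and Benjamini–Hochberg control across genes.
2. **Four-way set logic and fold-change quadrants**
   (`gutreg.concordance`): genes significant on both the microbiota axis
   (log₂FC of GF over CV within WT) and the genotype axis (log₂FC of WT
   over Mut within CV) fall into quadrants such as
   *suppressed_activated* — suppressed by microbiota, activated by the TF —
   whose share among microbiota-suppressed genes is the headline fraction.
3. **Peak-to-gene association** (`gutreg.regions`): each peak is assigned
   to the single nearest gene TSS within 10 kb (summit if recorded, else
   midpoint; ties broken lexicographically), plus peak-set sharing across
   conditions and RPKM-normalized flanking-signal profile matrices.
4. **Enhancer/expression concordance**: a two-sided two-sample
   Kolmogorov–Smirnov test comparing CV/GF expression fold changes of
   genes near CV-enriched versus GF-enriched regulatory regions.
5. **Cross-species disease concordance** (`gutreg.orthologs`,
   `gutreg.deming`): one-to-one ortholog filtering and chaining,
   upper-tail hypergeometric enrichment P(X ≥ k) of TF-associated genes in
   disease gene lists, and Deming errors-in-variables regression of paired
   orthologous log₂ fold changes,

   m = (s_yy − δ·s_xx + √((s_yy − δ·s_xx)² + 4δ·s_xy²)) / (2·s_xy),

   with leave-one-out jackknife slope standard errors and one-sided normal
   z tests between slopes (δ = σ²_y/σ²_x, default 1).

Because the original sequencing data are not required, `gutreg.simulate`
generates every input with planted structure — per-gene effect classes,
condition-specific TF peaks, ortholog tables with dropout and paralog
noise, and disease lists tied to the planted genotype effect through a
configurable structural slope — so every stage is testable against ground
truth.  See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from gutreg import PipelineConfig, SimulationConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate=SimulationConfig(), seed=1))
d = report.data
print(d["coregulation"]["class_counts"])
print(round(d["coregulation"]["suppressed_activated_fraction"], 3))
print(d["ks_concordance"]["shift_sign"], d["ks_concordance"]["p"])
for fit in d["deming"]["fits"]:
    print(fit["label"], round(fit["slope"], 3), "+/-", round(fit["se_slope"], 3))
```

prints

```
{'suppressed_activated': 179, 'suppressed_repressed': 28, 'induced_activated': 191, 'induced_repressed': 18, 'not_coregulated': 1584}
0.865
1 1.3930296838234924e-79
WTCV/WTGF -0.073 +/- 0.076
MutCV/MutGF -0.042 +/- 0.072
MutCV/WTCV 0.779 +/- 0.014
MutGF/WTGF 0.798 +/- 0.014
MutCV/WTCV[bound] 0.786 +/- 0.017
MutCV/WTCV[unbound] 0.778 +/- 0.025
```

Reading: of 207 genes classified as microbiota-suppressed and
TF-coregulated, 86.5% are TF-activated (the generator plants 90%); genes
near CV-gained enhancers are shifted toward higher CV expression
(shift_sign +1, KS p ≈ 1e-79); and the Deming slope of disease log₂FC
against the planted genotype-axis comparison (MutCV/WTCV, 0.78) recovers
the planted structural slope 0.8 while the colonization-axis reference
(WTCV/WTGF) is flat — the separation the slope z-test quantifies.

The same pipeline runs from the command line:

```sh
gutreg simulate --seed 1 --outdir dataset/
gutreg run-all --config config.yaml --outdir out/     # report.json + TSVs
```

with `config.yaml` either naming a `dataset:` directory or carrying a
`simulate:` block; subcommands `diffexp`, `diffregion`, `associate`,
`compare-peaks`, `profile`, `concord`, `enrich` and `deming` expose the
individual stages on standard files (BED, bedGraph, headered TSV).

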