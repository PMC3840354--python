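# mpnpipe

Comparative metagenomic/metatranscriptomic analysis of
methylphosphonate-driven microbial succession.

Aerobic degradation of methylphosphonate (MPn) by marine bacteria releases
methane and is a candidate source of the ocean's surface methane
supersaturation.  In nutrient-amendment microcosm experiments, glucose +
nitrate drives a seawater community into phosphorus starvation; when MPn is
also supplied, bacteria carrying the C-P lyase pathway (the *phn* operon)
bloom, transcribe it heavily, and convert MPn to methane.  `mpnpipe`
implements the sequence-analysis side of such an experiment as a reusable,
tested pipeline, and ships a synthetic community simulator so every stage
can be validated against known ground truth without external databases.

The pipeline consumes BLAST-tabular hit tables (12-column `outfmt 6`
layout) against four reference catalogs (rRNA, sRNA, protein/taxonomy,
KEGG) and provides:

* **Read partitioning** — each read classed rRNA > sRNA > protein >
  unassigned at a bit-score gate *b* ≥ 50.
* **Taxonomic profiles** — best-hit assignment of uniquely assignable
  reads; cross-taxon score ties excluded and counted.
* **KO / pathway profiles** — equal-top-score ties split 1/k per read;
  pathway abundance as the sum of member-KO percents; custom pathways
  (alkylphosphonate metabolism, phosphate metabolism, PHA biosynthesis)
  alongside standard ones; average-linkage clustering of samples on
  1 − Pearson *r*.
* **Differential abundance** — the Audic–Claverie conditional count test.
  Given count *x* in a library of size *N₁*, the count *y* in a library of
  size *N₂* follows

  ```
  p(y|x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) )
  ```

  evaluated as negative-binomial tail masses in log space, with
  Benjamini–Hochberg FDR and fold changes.
* **Gene-family abundance** — length-normalized counts relative to the
  single-copy gene *recA*, read as "percent of bacteria carrying the
  family": `100·(c_f/L_f)/(c_recA/L_recA)`.
* **Expression ratios** — per-gene (RNA share)/(DNA share) for genes on
  recovered C-P lyase clusters, grouped C-P lyase vs other.
* **Cluster annotation** — rule-based *phn* operon completeness
  (transporter phnC–E, catalytic core phnG–M, PRcP hydrolysis via phnP or
  rcsF) and phosphonate growth predictions.

## Worked example

Simulate the default microcosm scenario (three arms × five timepoints ×
paired DNA/RNA, 20,000 reads per library) and run the full pipeline:

```sh
mpnpipe run-all --scenario default --seed 13 --out out/
```

or, from Python, reproduce the headline statistic — the fraction of
bacteria carrying C-P lyase genes, estimated from DNA libraries by recA
normalization:

```python
from mpnpipe.simulate import default_scenario, simulate
from mpnpipe.genefamily import family_abundance, family_group_mean

sim = simulate(default_scenario(seed=13))
six = ["phnG", "phnH", "phnI", "phnJ", "phnM", "phnN"]
for lib in ["control_00h_DNA", "control_48h_DNA", "GlcN_48h_DNA", "GlcN_MPn_48h_DNA"]:
    ab = family_abundance(sim.hit_tables[lib]["protein"], sim.catalog, six)
    print(lib, round(family_group_mean(ab, six), 1))
```

prints

```
control_00h_DNA 1.8
control_48h_DNA 2.1
GlcN_48h_DNA 7.1
GlcN_MPn_48h_DNA 44.6
```

— C-P lyase carriage is near zero at the start and in the control, small
under Glc+N alone, and ≈45% of bacteria after 48 h with MPn (the
simulator's true endpoint carriage is 46%; *recA* itself always normalizes
to exactly 100).  The numbered drivers under `analysis/` walk the same
simulation through every stage and write their tables under
`results/analysis/`: the opportunist *Vibrionales* bloom at 24 h, amended
24–48 h transcriptomes clustering apart from the controls, the
alkylphosphonate pathway as the top fold-change pathway only in the MPn
arm at 48 h (≈1100-fold over control), C-P lyase hits attributed ≈52%/45%
to the two carrier orders, and a C-P lyase mean expression ratio ≈11-fold
above the carriers' other genes.

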