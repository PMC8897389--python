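# gammatc

Time-course transcriptome analysis of γ-irradiated primordial oocytes.

Resting (dictyate-arrested) oocytes answer DNA damage with a fast,
p63-driven death program: the TAp63α sensor converts from a closed dimer
to an active tetramer within hours of irradiation, and the transcriptome
shifts accordingly. This package re-implements, as a reusable and tested
pipeline, the computational analysis of that response over a
0 / 1 / 2.5 / 4 / 6 h design (duplicates at 0, 1 and 4 h; single
libraries at 2.5 and 6 h; 0.5 Gy high-dose and 0.2 Gy low-dose arms):

1. **counts** — pseudocount tables + sample sheet, transcript→gene
   aggregation, pairwise Pearson QC on log2(x+1);
2. **differential expression** — a deliberately simple negative-binomial
   stage for the mixed replicated/unreplicated design: median-of-ratios
   size factors; per-gene method-of-moments dispersions shrunk toward a
   trended log–log mean–dispersion fit; a delta-method Wald test of each
   time point against 0 h on moderated log2 fold changes; per-contrast
   Benjamini–Hochberg; DEGs at |log2FC| > 1 and adjusted p < 0.05
   (protein-coding only);
3. **temporal clustering** — each DEG's exact set of significant time
   points maps it onto one of eight Venn-membership clusters
   (Cl1 {1}, Cl2 {2.5}, Cl3 {4}, Cl4 {6}, Cl5 {4,6}, Cl6 {2.5,6},
   Cl7 {2.5,4,6}, Cl8 {1,2.5,4,6}) or "ungrouped"; up/down split by mean
   log2FC sign; z-scored profiles for heatmaps;
4. **GO enrichment** — hierarchy levels on the biological-process DAG
   (level = 1 + shortest is_a path to the root), level-3 terms
   aggregated into ~20 umbrella labels, per-cluster hypergeometric
   overrepresentation with enrichment factors (k/n)/(K/N), word-cloud
   font scaling, and keyword word-mining (apoptosis / necro(pto)sis /
   DNA damage and repair);
5. **comparisons** — case-normalized literature gene-list overlaps,
   sample PCA with variance fractions, per-gene fold summaries, ΔΔCt
   qPCR fold induction (2^−ΔΔCt against a housekeeping reference), and
   per-cluster mean z-profiles per dose for the low-vs-high-dose
   kinetics;
6. **motif scan** — ±2 kb promoter windows around each TSS scanned on
   both strands with p53-family position-weight matrices; a hit's
   similarity is the min–max-normalized log-odds score, thresholded at
   0.85.

A synthetic-data module generates every input the pipeline consumes —
NB counts with planted cluster-shaped effects and a truth table, a toy
GO DAG with known depths, a toy genome with planted motif consensi, and
qPCR plates — so the whole analysis runs end to end on a desk.

## Worked example

```sh
python analysis/01_simulate.py --seed 1        # fixtures under results/fixtures
python analysis/02_differential_expression.py  # DE tables under results/02_de
python analysis/03_temporal_clusters.py
python analysis/04_go_enrichment.py
python analysis/05_literature_dose_comparison.py
python analysis/06_motif_scan.py
```

Step 03 prints, for the default seed:

```
39 DEGs, 97% grouped into Cl1-Cl8
planted cluster+direction recovery: 100.0% of 32 planted genes
```

meaning all 32 genes planted with 8-fold effects at their pattern's time
points came back with exactly the planted cluster label and direction
(the handful of extra DEGs are false positives at the expected rate).
Step 05 prints the headline numbers re-derived from study-shaped
stand-in tables:

```
stand-in tables: 167 protein-coding DEGs, 151 grouped (90%)
  overlap with p53_targets (64 genes): 8
  overlap with ipsc_down (241 genes): 3
  overlap with ipsc_up (296 genes): 8
  mean fold at 2.5 h (apoptosis genes): 1.33; pre-irradiation group: 1.60
  PCA of both dose arms: PC1-3 explain 80% of variance
```

and step 06 reports every planted promoter consensus found at
similarity 1.0. The same stages are scriptable through the `gammatc`
CLI (`simulate`, `de`, `cluster`, `enrich`, `compare`, `scan`, `all`)
from a single YAML config.

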