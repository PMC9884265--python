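# heatloop

Desk-scale analysis of how heat stress reorganizes the three-dimensional
genome of a plant (the motivating system is tomato leaf tissue under a
0 h / 1 h / 6 h heat time course). The package implements the full analysis
chain used in such studies — A/B compartment analysis from Hi-C, significant
promoter–enhancer interaction calling from capture Hi-C and RNAPII HiChIP,
regulatory-element classification from ATAC-seq and histone marks, TF-network
inference, and quantification of 3C-qPCR and dual-luciferase validation
assays — together with a seeded synthetic-data generator that plants known
compartments, loops, signatures and effect sizes so every stage is testable
without any sequencing data.

It is written for computational biologists who want a small, transparent,
fully testable implementation of these methods: every statistic is a plain
function over numpy/pandas containers, and every claim the test suite makes
is checked against planted ground truth or an independent brute-force oracle.

## The models in brief

* **Compartments.** For a binned intrachromosomal contact matrix `M`, the
  expected contact at distance `d` is the diagonal mean; `O/E = M_ij / E(|i−j|)`
  removes the polymer distance decay. PC1 of the column-centered Pearson
  correlation of O/E rows is the compartment axis; its sign is oriented so
  that A (PC1 > 0) carries the higher activity-track signal (H3K9ac). Saddle
  plots average O/E between PC1 quantile groups; compartment strength is
  `(AA·BB)/(AB·BA)` over the corner means.
* **Interaction calling.** A cumulative-binomial model in the HOMER family:
  `E[k_ij] = b_i · b_j · f(|i−j|)` with per-bin biases `b` and decay `f`
  estimated jointly from the matrix (the product form absorbs capture and
  antibody bias), `p0 = E[k_ij]/Σ E`, and the p-value is the binomial upper
  tail `P(X ≥ k_ij)` with `X ~ Bin(N, p0)`, BH-corrected at α = 0.05.
  Differential interactions between conditions use Fisher's exact test on
  depth-conditioned counts. APA stacks O/E windows around loop anchors; the
  center score divides the center pixel by the short-distance background
  corner.
* **Regulatory elements.** Accessible peaks split into TSS-proximal
  (strand-aware 1.0 kb upstream window), TSS-distal (≥ 1 kb from every gene)
  and genic; distal peaks whose nucleosome flanks are high in H3K9ac and
  H3K18ac (cohort quantile ≥ 0.75) and devoid of H3K4me3 (≤ 0.25) are labeled
  enhancer-like. Accessibility time courses are clustered with seeded k-means
  (k = 5) and a batch self-organizing map.
* **Motifs and networks.** PWMs built from IUPAC consensus strings (the heat
  shock element `TCTAGAANNTTCT` ships as the example) are scanned by
  log-odds on both strands; enrichment compares peaks against length-matched
  random genomic windows with a binomial tail. A TF→gene edge at time *t*
  requires a motif hit in a peak on the gene's promoter, accessibility of
  that peak at *t*, and differential expression of the gene at *t*.
* **Assays.** 3C-qPCR relative interaction frequency is `E^−(Ct_target −
  Ct_norm)` against an uncut control region, technical replicates averaged
  before biological, scaled so the reference group (wild type, 0 h) is 1.
  Luciferase activity is the LUC/REN ratio normalized to the minimal-promoter
  control. Group comparisons use the pooled-variance two-sample Student's
  t-test.

## Worked example

```python
from heatloop import compartments as cp, interactions as ix
from heatloop.synth import SynthConfig, generate_dataset

ds = generate_dataset(SynthConfig(), seed=7)

# compartments from the 0h Hi-C map
cm = ds.contacts[("HiC", "0h")]
oe = cp.oe_by_chrom(cm)
corr = {c: cp.correlation_map(m) for c, m in oe.items()}
prof = cp.compartment_pc1(corr, ds.tracks["H3K9ac"])
sad = cp.saddle(oe, prof)
print(f"saddle strength (0h): {sad.strength:.2f}  "
      f"AA={sad.corner_means['AA']:.2f} BB={sad.corner_means['BB']:.2f}")

# promoter-interaction calling on the 1h capture Hi-C map
chic = ds.contacts[("CHiC", "1h")]
calls = ix.call_interactions(chic, min_dist_bins=2, max_dist_bins=100, correction="BH")
print(f"significant interactions at 1h: {len(calls)}")

# aggregate signal over the planted heat-gained loops
gained = [(l.chrom, l.bin1, l.bin2) for l in ds.truth.loops if l.hsfa1a]
for cond in ("0h", "1h"):
    score = ix.apa(ds.contacts[("HiC", cond)], gained).score
    print(f"APA center score over heat-gained loops ({cond}): {score:.2f}")
```

prints

```
saddle strength (0h): 5.52  AA=1.45 BB=1.48
significant interactions at 1h: 507
APA center score over heat-gained loops (0h): 0.81
APA center score over heat-gained loops (1h): 2.36
```

The strong saddle corners reflect the planted checkerboard; the APA score
near 1 at 0 h versus ~2.4 at 1 h shows the transient, heat-induced
promoter–enhancer loops appearing only under stress, exactly as planted by
the generator.

A command line mirrors the library (`heatloop simulate`, `heatloop
compartments pc1|saddle|scaling|diff`, `heatloop loops call|diff|apa|hubs|
strata`, `heatloop re ...`, `heatloop tf ...`, `heatloop assay 3c|luc`,
`heatloop run-all`). `heatloop run-all --seed 7 -o results/` executes every
stage and writes `report.json` with the headline metrics.

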