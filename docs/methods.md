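# Methods

This note documents the models implemented in `heatloop`, the study
conditions encoded in the synthetic-data generator, the numerical choices
that were genuinely open, and the limits of what the passing test suite
shows.

## Coordinates and containers

All coordinates are 0-based, half-open (BED-native; GFF3 input is converted
on read). The strand-aware TSS of a `-` gene is its annotation end
coordinate, and promoters extend 1.5 kb upstream in strand direction.
Contact matrices are dense per-chromosome symmetric arrays — at desk scale
(hundreds of bins per chromosome) sparsity buys nothing. Interval overlap
arithmetic is done directly in numpy; the interval sets here are small
enough that an interval tree would be overhead.

## Matrix balancing

Iterative proportional fitting per chromosome (tolerance 1e-3 on the
unmasked row-sum spread, at most 200 iterations). Bins with a raw marginal
below 5% of the median nonzero marginal are masked to NaN first; on
non-convergence the best iterate is returned and flagged. Balanced matrices
are scale-free, so a global factor on the input does not change the result.

## Compartment analysis

* **Expected/decay model**: the per-distance mean of the matrix. O/E divides
  by it, which makes every diagonal of O/E average to 1 by construction and
  makes O/E invariant to sequencing depth.
* **PC1** is the leading eigenvector of the column-centered (then
  re-symmetrized) Pearson-correlation map of O/E rows, computed per
  chromosome — compartment structure is an intrachromosomal signal at this
  scale, and per-chromosome maps avoid trans-contact assumptions. A leading
  eigengap below 1e-8 (relative) marks the chromosome degenerate and masks
  it: with no spectral gap there is no stable compartment axis.
* **Sign convention**: eigenvector signs are arbitrary, so the axis is
  oriented by an activity track (H3K9ac by default): A is the side with the
  higher mean activity. Published conventions differ (some plot −PC1); the
  orientation source is recorded in the profile.
* **Saddle**: genome-wide equal-occupancy PC1 quantiles (Q = 50), pairs
  closer than 2 bins excluded, corner size 5. Strength defaults to the
  corner-mean ratio product (AA·BB)/(AB·BA); the additive variant
  (AA+BB)/(AB+BA) is also reported. On compartment-free data the strength of
  a single simulation fluctuates around 1 by roughly ±5–10% — ranking bins
  by a PC1 that was fitted on the same finite contact sample selects
  correlated noise into the corners. This is a property of saddle analysis
  itself, not of this implementation; the null-calibration check therefore
  averages over 12 independent simulations at 10⁷ pairs per chromosome,
  where the mean is unbiased well within ±0.05.
* **Scaling curves P(s)**: mean contacts per bin pair in log2-spaced
  distance bins, reported per million valid pairs. Pairs are taken within
  each contiguous run of the region class — an "arm" curve never mixes in
  centromere-spanning contacts, which belong to neither arm. The log-log
  slope is fitted from 3 bins to a quarter of the largest region span, the
  regime where the curve is well sampled; curve comparisons between
  conditions are made over the same fitted range.
* **Difference maps** normalize both matrices to counts per million
  intrachromosomal valid pairs before subtracting, so pure depth differences
  cancel exactly.

## Interaction calling

The caller follows the cumulative-binomial family: the expected count of a
bin pair is `b_i · b_j · f(d)`. Raw marginals are a poor estimate of `b`
when bias is spatially clustered (a bin's marginal absorbs its neighbours'
capture bias through the decay), so biases and decay are estimated jointly
by alternating updates — `f(d)` as the pooled per-distance ratio of counts
to the current bias product, then `b_i` matched to the off-diagonal marginal
(the diagonal scales with the squared bias and is excluded). The fixed point
factorizes any multiplicative bin bias exactly; on simulated capture Hi-C
with 5× per-end bait enrichment the model is calibrated to an
observed/expected ratio of 1.00 across bait classes. Non-factorizable
structure — the compartment checkerboard itself — is deliberately not
absorbed: A–A pixels are genuinely enriched and are called, which matches
how this caller family behaves on real data. Recovery statistics for
planted loops are therefore measured on decay-only constructions where
"non-loop" has an unambiguous meaning.

Expected probabilities are renormalized to sum to 1 over the tested pairs
and N is the total tested count, so the restricted model is itself
multinomial. P-values use the regularized-incomplete-beta binomial tail;
they match a brute-force log-space tail summation to 1e-12 relative for
N ≤ 2000. Correction is BH by default; the raw p ≤ 0.05 threshold used by
the original caller family is selectable.

Differential calls use two-sided Fisher's exact tests on
`(k_b, N_b − k_b; k_a, N_a − k_a)` with BH; "gained" means enriched in the
second (treatment) condition. The test is symmetric under group swap with
the direction label inverted.

**APA** stacks (2w+1)×(2w+1) O/E windows (w = 5) over loop pixels at least
2w+1 bins apart and w bins from edges; the score is the center pixel over
the mean of the 3×3 lower-left (short-distance) corner, the common
convention. Two caveats, both visible in synthetic data and documented here
because they affect real analyses equally: (i) a checkerboard compartment
background modulates O/E differently at the center distance and the corner
distance, biasing the absolute score when anchors sit in structured
regions — quantitative fold recovery is therefore assessed on
compartment-free constructions, while condition *comparisons* (1 h vs 0 h)
are assessed on the full preset, where the background bias cancels between
conditions; (ii) loops planted on a regular lattice can leak into each
other's background corners, so the generator places loops along a (1, 2)
lattice direction that never intersects the corner window.

## Regulatory elements

Proximal = overlapping the strand-aware `[TSS−1000, TSS)` upstream window
(linked to the nearest-TSS gene); distal = at least 1 kb from every gene
body; everything else genic-other, because "further away from genes"
excludes gene bodies — a flag allows genic distal if wanted. The
enhancer-signature rule uses ±500 bp flanks outside the accessible interval
and cohort quantiles (hi 0.75 on H3K9ac and H3K18ac, lo 0.25 on H3K4me3)
rather than absolute thresholds, since mark levels are only qualitatively
specified ("high", "devoid"). The rule is monotone: raising H3K4me3 above
the low quantile removes the label, and proximal peaks are never labeled.

k-means uses seeded k-means++ with Lloyd iterations (tol 1e-6, ≤300
iterations) on row-standardized profiles (the published portraits show
shape, not magnitude), clusters relabeled by descending size. The SOM is a
batch map with PCA-span initialization, Gaussian neighbourhood, and radius
decaying linearly from max(grid)/2 to 0.5 over 50 epochs; the quantization
error is recorded after each epoch's update and is non-increasing in
practice under the decaying radius.

## Motifs and the TF network

PWMs come from IUPAC consensus strings with pseudocount 0.01; N columns
score as background. The default hit threshold is 75% of the maximal
log-odds score — sharp consensus PWMs have bimodal score distributions, so
recovery is insensitive to the exact fraction. Scanning is exhaustive on
both strands and agrees bit-for-bit with a brute-force per-window scorer.
Enrichment uses 10,000 length-matched random genomic windows excluding peak
overlaps; a zero background rate is floored at 1/draws and flagged.

Network edges require the conjunction (motif hit in a promoter-overlapping
peak) ∧ (peak accessible at t) ∧ (gene DE at t); output is a time-layered
directed multigraph, independent of input record order. Percentages in the
target-regulation split are round-half-up at one decimal.

## Assays

Relative interaction frequency assumes amplification efficiency 2
(exposed as a parameter): `RIF = E^−(Ct_target − Ct_norm)`, normalization Ct
from a restriction-site-free region. Technical replicates are averaged
before biological ones — with balanced designs this equals flat averaging —
and each loop is scaled so the reference group (wild type 0 h) has mean 1.
Luciferase: per-replicate LUC/REN, construct means normalized to the
minimal-promoter control. The t-test is the pooled-variance Student's form
(the published analyses specify a two-sample Student's test); Welch is
available behind a flag. Zero pooled variance with equal means returns
(t=0, p=1); with unequal means the p-value is floored at the smallest
positive float and flagged.

## The synthetic study

The generator encodes the study conditions once; its defaults are not
tuning knobs. Two 5 Mb chromosomes at 20 kb bins; a central 0.6 Mb
pericentromere, entirely B compartment; arms in alternating 500 kb (25-bin)
A/B blocks with the block adjacent to the pericentromere always A and
partial chromosome-end blocks always B, which balances A–A and B–B pair
counts within arms. Contacts are a single multinomial draw of 10⁶ pairs per
chromosome over weights

```
w_ij ∝ d^−γ · (1 + a·χ_i χ_j) · heat(i,j) · loops(i,j) · assay(i,j)
```

with γ = 1 (d ≥ 1; the diagonal gets weight 1), checkerboard amplitude
a = 0.4, and at 1 h an A–A boost ×1.3 and B–B damping ×0.7 that revert at
6 h. Because arms are ~50/50 A/B per distance, these modifiers leave the
per-distance arm mean essentially unchanged while the all-B pericentromere
drops by ~×0.73 — the directional pattern the analysis must recover. Twenty
loops are planted between promoter and distal-RE anchors ≥7 bins inside A
blocks: ten heat-gained (fold 3 at 1 h only, flagged HSFA1a-bound and
RNAPII-associated) and ten stable (fold 3 throughout). Capture Hi-C
multiplies a per-end ×5 bait efficiency at gene-containing bins; RNAPII
HiChIP adds fold 3 at RNAPII-flagged loop pixels.

Peaks: one proximal peak per gene (260 genes), 300 distal peaks in
gene-free A-compartment bins (30 with the planted enhancer signature:
flank H3K9ac/H3K18ac at level 8 versus a gamma background, H3K4me3 at 0.15,
i.e. genuinely devoid), 40 genic peaks. Accessibility time courses follow
five archetypes (up/down × transient/sustained, late-up) whose 0 h/6 h
levels differ by 0.25 log2 units — enough to break rank ties so rank
correlations are well defined, small enough that transient genes stay
reverted (|log2FC| < 0.3) and below DE thresholds. Expression is negative
binomial (dispersion 0.05, depth 10⁶, two replicates as in the motivating
study) with gene log2 fold changes tied to the linked peak's archetype. The
TF cascade plants a heat-shock-factor layer (15 genes, accessible and
induced at 1 h, HSE consensus in the promoter peak) and a late layer
(15 genes at 6 h) carrying a tandem W-box 12-mer — a synthetic stand-in for
the 6 bp WRKY site, which is too short for exact-recovery testing in a
10 Mb genome. DAP peaks sit 800 bp upstream of target TSSs, outside the
proximal ATAC peaks, so planted binding-site motifs cannot create network
edges on their own. qPCR tables encode wild-type 1 h/0 h fold 2.5 and
knock-down fold 0.6 with Ct noise sd 0.15 over 3×3 replicates; luciferase
constructs have folds 2.5 and 3.5 over the control at n = 3. The 247-gene
knock-down DE table (186 down / 61 up) enters as configured truth — it is a
printed input, and the split operation recomputes the percentages from it.

One master seed expands into fixed, labeled substreams (seed, CRC32 of the
component name), so adding a component never perturbs existing draws and
identical seeds give byte-identical datasets.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: restriction-fragment artifacts and ligation
noise; unmappable or copy-number-variable bins; TADs and loop extrusion;
trans-chromosomal contacts; correlated replicate structure and batch
effects; realistic motif degeneracy and chromatin-state heterogeneity
within a class; tissue mixtures. Recovery rates measured here are
upper bounds for well-specified models on clean data.

## Problem sizes

All analyses run at the desk-scale preset (2 × 5 Mb at 20 kb ≈ 250 bins per
chromosome, 10⁶–10⁷ pairs per chromosome, 600 peaks, 260 genes). The full
test suite takes under a minute; the acceptance script regenerates
everything from scratch in well under a minute.

## Known limitations

* The binomial caller's factorized background cannot represent compartment
  enrichment; on strongly compartmentalized maps it calls A–A pixels, as its
  real-data counterparts do. Interpret genome-wide call counts accordingly.
* Absolute APA scores are biased by structured backgrounds (above);
  condition ratios are the robust quantity.
* The simple DE procedure is an unmoderated per-gene t-test: at two
  replicates it has essentially no power at BH 0.05 and is intended as
  plumbing for downstream stages, not as a DESeq2 substitute.
* 3C-qPCR quantification assumes perfect amplification efficiency unless
  told otherwise, and implements only uncut-region normalization (no
  random-ligation control template).
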