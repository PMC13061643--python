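# Methods

This note documents the models and procedures implemented in `trimark`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Border detection

**Model.** A locus is represented by one fixed-width binned pseudobulk
signal track per modality (ATAC, H3K27ac, H3K27me3), CPM-normalized per
group. Signal is assumed piecewise-stationary: a small number of step
changes separated by segments of roughly constant rate, with per-bin
counts behaving like (over)dispersed Poisson draws.

**Statistic.** Each track is mean-normalized and square-root
transformed. The square root serves two purposes: Poisson-like noise
becomes homoscedastic (the sd of √count is ≈ 1/2 regardless of level), so
a single noise scale applies across low-signal flanks and high-signal
blocks; and a uniform rescaling of the track multiplies both the signal
and the noise scale by the same constant, so the z score is exactly
normalization-free. Detection then follows a smoothed-derivative scheme:
Gaussian smoothing (σ bins), first difference, and a robust z score.

The noise scale is estimated from the *raw* first differences of the
transformed track, `σ̂ = 1.4826·MAD(Δu)/√2`, and propagated to the
smoothed differences by multiplying with the ℓ2 norm of the differenced
smoothing kernel. Estimating on raw differences matters: each true step
contaminates only one raw difference, so the MAD is essentially clean,
whereas after smoothing a handful of steps can occupy near half of the
differences on a compact locus and inflate a MAD computed there several
fold, suppressing genuinely significant medium-sized steps. This scale
choice is the one place where the detector departs from the most naive
formulation; it was adopted because the naive smoothed-difference MAD
demonstrably fails to separate two-fold steps from noise on compact loci
with a few large transitions.

**Calling.** Candidates are local maxima of |z| at or above the
threshold; plateaus resolve to their leftmost bin. Candidates closer than
the minimum separation are merged greedily, strongest first, ties to the
leftmost. The boundary position is the first bin of the new segment
(`diff[i]` assigns the step to bin `i+1`); direction is the sign of the
difference. On a noise-free track the scale estimate is zero; any
non-zero step is then treated as significant by substituting a tiny
scale proportional to the largest difference, which keeps localization
by local maxima intact. Tracks shorter than 3 bins are rejected.

**Parameters** (`BorderParams`, all in bin units):

| parameter        | default | meaning / rationale |
|------------------|---------|---------------------|
| `sigma`          | 3       | smoothing bandwidth; ~6 kb at 2-kb bins, narrow enough to keep transitions 12 kb apart separable |
| `z_threshold`    | 4       | robust-z detection threshold; with a clean noise scale, planted fixture steps score z ≈ 7–50 while noise maxima stay near 4, so occasional single-modality false calls are possible at this depth but three-modality grades are stable |
| `min_separation` | 5       | within-modality merge radius; below the 6-bin width of the narrowest fixture segment |
| `tolerance`      | 2       | cross-modality single-linkage distance for border aggregation |

## Border grading and domain classification

Boundaries from all modalities are pooled, sorted by bin, and chained
into clusters wherever consecutive boundaries are within the tolerance
(single linkage). Within a cluster each modality contributes at most
once — its largest-|z| member — and the border's grade is the number of
distinct supporting modalities: weak (1), moderate (2), strong (3). The
border position is the mean of the kept members' positions. Direction
and amplitude are recorded but do not enter the grade.

Domains are the intervals between consecutive borders (or track ends).
Each domain's per-modality mean CPM is expressed as fold over the mean of
the same modality in a caller-supplied baseline interval of flanking
chromatin. The rule is evaluated in order:

* **silenced** — H3K27me3 fold ≥ `high_thresh` (4) and ATAC fold <
  `act_thresh` (2): heavy repression without accessibility;
* **primed** — ATAC fold ≥ 2 and H3K27ac fold ≥ 2 and H3K27me3 fold ≥
  `mid_thresh` (1.5): accessible, actively marked chromatin that still
  carries an intermediate repressive load;
* **inactive** — otherwise.

The thresholds encode ordinal relations (primed repression above flanking
chromatin but far below the silenced block) rather than absolute levels;
they are exposed on the model. A baseline interval with zero signal in
any modality raises an error instructing the caller to add a pseudocount
or choose a covered interval, rather than silently producing infinite
folds.

## Synthetic data

The generator produces a single ~1-Mb toy chromosome with a 13-gene
cluster (one gene per 12 kb) and 20 marker genes per simulated cell type
placed far from the cluster. The cluster and its 50-kb flanks are tiled
by six segments whose (ATAC, H3K27ac, H3K27me3) rates — expected
fragments per cell per 2-kb bin — are

```
s0 flank        0.05 0.05 0.10      s3 genes 7–9    0.40 0.40 0.70
s1 genes 1–4    0.60 0.60 0.25      s4 genes 10–13  0.05 0.05 1.20
s2 genes 5–6    0.40 0.40 0.40      s5 flank        0.05 0.20 0.30
```

realizing, in order, a three-modality entry transition, a second
three-modality step, an H3K27me3-only step, a strong primed→silenced
switch, and a two-modality exit — i.e. planted grades 3, 3, 1, 3, 2. The
magnitudes are free parameters chosen to realize those ordinal relations;
only the relations are structural. Counts are Poisson by default
(negative binomial with dispersion 0.3 as an option — Poisson is the
minimal count model when no overdispersion estimate is available).
Fragment lengths are a subnucleosomal/mononucleosomal normal mixture
(modes 80/200 bp, weight 0.4). A configurable fraction of cells
(default 0.3) forms "group 2" with 3′ (s1–s3) H3K27me3 reduced to the
flanking rate while H3K27ac is drawn identically in both groups, so the
groups are separable by H3K27me3 alone and H3K27ac is exchangeable by
construction.

Contact matrices are Poisson around a `decay_scale/(1+d)` distance decay
(`decay_scale` 200 at 10-kb bins), multiplied by 2 within TADs and 3 at
planted loop-anchor pixels. The single-TAD scenario covers the cluster
±20 kb in one block; the split scenario divides it at the mid-cluster
border (the primed/silenced junction). Note that ICE balancing absorbs
part of a block enrichment, so the planted 2× factor appears as roughly
1.25× in balanced O/E terms; generator-level enrichment checks are
therefore made on distance-matched raw counts.

**What the generator does not emulate:** read-level sequence, FASTQ,
barcode errors, doublets, mappability or GC biases, peak structure within
segments (rates are flat per segment), genome-wide background beyond one
chromosome, and trans-chromosomal contacts. Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistics under the assumed count model — not robustness to artifacts of
real sequencing data.

## Supporting computations

* **Binning** credits a fragment's `count` to the bin of each insertion
  terminus (`start` and `end−1`), conserving `2·Σcount` exactly; unknown
  barcodes are dropped and tallied. All coordinates are 0-based
  half-open.
* **TSSe** is a center/background insertion-rate ratio: ±100 bp around
  the TSS over the outermost 100 bp of the ±2-kb window, pooled over
  TSSs per cell. Cells with zero background are flagged with score 0.
  QC retention is strict (`TSSe > 7`, `fragments > 3000` at sequencing
  scale; the demo uses depth-appropriate values on the simulated locus).
* **Pseudobulk** tracks are per-group bin sums scaled to CPM over the
  track extent (each track sums to 1e6). Smoothing is Gaussian with
  reflected boundaries, which conserves total mass exactly.
* **Within-cell grouping** uses 1-D two-means on per-cell depth
  normalized (counts per thousand) H3K27me3 in the region, initialized
  deterministically at the 10th/90th percentiles; the split is refused
  (single group, diagnostic message) when values are indistinguishable or
  the iteration collapses, rather than forcing two groups. A mean
  silhouette is reported as a separation diagnostic. The H3K27ac equality
  test is a two-sided label-permutation test with the add-one p-value
  `(1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm)`.
* **ICE balancing** pre-masks bins with under 2% non-zero pixels,
  iterates division by the outer product of row sums (renormalized to
  mean 1) until the max relative row-sum deviation is below `tol`
  (default 1e-5, max 200 iterations), and reports the residual on
  non-convergence while keeping the best iterate. Expected-by-distance is
  the per-diagonal mean over unmasked pixels; the compartment eigenvector
  is the leading eigenvector of the Pearson correlation of log O/E with
  its sign anchored to a reference track (e.g. ATAC coverage).
* **Insulation** sums balanced contacts in the w×w diamond with corner
  at bin b (`i ∈ [b−w, b), j ∈ (b, b+w]`, `w = window/bin`), scores
  `log2(sum / chromosome mean)`, and calls boundaries at local minima
  with prominence ≥ 0.2 (log2 units). The normalization and prominence
  default are conventions chosen for comparability; only the window and
  bin sizes (100 kb / 10 kb) are externally fixed.
* **Differential accessibility** is a two-sided Welch t-test on log1p
  CPM per feature with BH correction across features;
  `logFC = log2((meanCPM_A+1)/(meanCPM_B+1))`; significance defaults are
  adjusted p ≤ 0.001 and |logFC| ≥ 1.5. Welch's unequal-variance form
  was chosen because per-cell depth differences make pooled-variance
  assumptions fragile; features with zero variance in both groups get
  p = 1.
* **Metagene scores** are means of per-gene z-scored activity over a
  marker set (z-scoring prevents high-activity genes from dominating);
  ties and all-zero cells are left unlabeled with a flag. Optional k-NN
  smoothing of the activity matrix (PCA space) is off by default.
* **TF strength** is out-degree minus in-degree; parallel edges collapse
  by default with a multiplicity-weighted option; self-loops are
  excluded by default. Ranking ties break alphabetically so tables are
  deterministic.

## Problem sizes

The test suite and the acceptance script use the generator's study
conditions directly: 500 cells per modality for the reference fixture
(20 replicate seeds for the stability check), 300+300 cells for the
differential calibration with 50 planted 8-fold bins, 500 null fixtures
of 50+50 values with 199 permutations each for the type-I error rate,
and 100-bin contact matrices at 10-kb resolution. The full suite runs in
well under a minute on one CPU.

## Known limitations

* The border detector assumes approximately piecewise-constant signal;
  gradual ramps are reported as one or more step calls depending on σ.
* Grades count modalities only; a very large single-modality step and a
  barely-threshold one are both "weak". Amplitudes are retained on the
  border objects for callers who want a weighted notion of strength.
* Domain classification depends on the chosen baseline interval; a
  baseline overlapping a real domain shifts all folds.
* Insulation near masked bins uses available pixels only (NaN-aware
  sums); boundaries within one window of the matrix edge are not called.
* At the default depth (500 cells) occasional single-modality false
  borders occur (z marginally above threshold); they subdivide but do
  not relabel the macro domains.
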