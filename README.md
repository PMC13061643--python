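# trimark

Joint single-cell chromatin analysis across three modalities — ATAC
accessibility, H3K27ac (active) and H3K27me3 (Polycomb-repressive) histone
marks — for detecting **graded signal borders** and classifying the
intervening chromatin as **inactive, primed or silenced**.

The package is aimed at epigenomics analysts working with multimodal
single-cell data (joint CUT&Tag-style histone profiling plus snATAC), in
particular at developmental loci such as HOX clusters where accessibility
and the two K27 marks change in coordinated, collinear steps. It also
bundles the supporting computations such an analysis needs: fragment-file
I/O and insertion-based binning, per-cell TSS-enrichment QC, pseudobulk
CPM tracks, within-cell mark grouping with a permutation test,
contact-matrix analytics (ICE balancing, observed/expected, compartment
eigenvector, diamond insulation, virtual 4C, aggregate loop pileup),
TF-network strength statistics, and pseudoreplicate differential
accessibility with Benjamini–Hochberg correction. A synthetic-data
generator emulates the full study design so every stage is testable
without any external download.

## The model

For each modality, the pseudobulk CPM track over a locus is screened for
signal boundaries with a robust changepoint score. With track values
$v_1,\dots,v_n$ per fixed-width bin:

1. variance stabilization: $u_i = \sqrt{v_i / \bar v}$ — count noise
   becomes homoscedastic and the score is exactly invariant to uniform
   rescaling of the track;
2. Gaussian smoothing with bandwidth $\sigma$ bins: $s = G_\sigma * u$;
3. robust z score of the first difference,
   $z_i = (s_{i+1} - s_i) / (c_\sigma\,\hat\sigma_u)$, where
   $\hat\sigma_u = 1.4826\,\mathrm{MAD}(\Delta u)/\sqrt2$ estimates the
   per-bin noise sd from raw first differences and $c_\sigma$ is the
   $\ell_2$ norm of the differenced smoothing kernel;
4. boundaries are local maxima of $|z|$ at or above a threshold (default
   4), greedily merged within a minimum separation.

Boundaries from the three modalities are then clustered by single linkage
within a bin tolerance; each cluster is a **border** whose *grade* is the
number of distinct supporting modalities — weak (1), moderate (2), strong
(3). The domains between consecutive borders are classified from their
per-modality mean signal expressed as fold over a flanking baseline
interval: *silenced* if the H3K27me3 fold is ≥ 4 with ATAC fold < 2;
*primed* if ATAC and H3K27ac folds are ≥ 2 with H3K27me3 fold ≥ 1.5
(accessible and actively marked, yet retaining intermediate repression);
*inactive* otherwise. All thresholds are configurable.

## Worked example

Simulate the HOX-like fixture (13-gene cluster, upstream inactive flank,
primed 3′ block with internal sub-transitions, silenced 5′ block; 500
cells per modality) and fit the border model:

```python
import trimark as tm
from trimark import domains, pipeline

cfg = tm.SimConfig(seed=42, cells_per_type=500)
genome = tm.make_genome(cfg)
fixture = tm.make_hox_fixture(genome, cfg)
tracks = pipeline.fixture_tracks(fixture)          # CPM pseudobulk per modality
model = domains.ChromatinDomainModel(
    tracks, baseline_interval=(genome.locus[0], genome.cluster_start))
print(model.fit().summary())
```

```
Multimodal chromatin-domain border model
========================================================
locus: chrS:350000-606000
params: sigma=3.0 bins, |z|>=4.0, min_sep=5, tolerance=2

Borders (grade = number of supporting modalities)
 position  bin  grade grade_name        modalities  max_abs_z
   400667   25      3     strong atac,k27ac,k27me3  53.455278
   448000   49      3     strong atac,k27ac,k27me3  12.600014
   472000   61      1       weak            k27me3  11.189931
   508000   79      3     strong atac,k27ac,k27me3  39.522388
   556000  103      2   moderate      k27ac,k27me3  43.815864

Domains
 start    end    state  fold_atac  fold_k27ac  fold_k27me3
350000 400667 inactive       1.39        1.41         1.04
400667 448000   primed      12.46       12.56         2.01
448000 472000   primed       8.40        8.43         3.30
472000 508000   primed       8.45        8.40         5.14
508000 556000 silenced       1.04        1.12        12.19
556000 606000 inactive       1.02        4.28         3.05
```

The five planted transitions are recovered at their planted positions
with the planted grades: three strong borders (all three modalities step
together at the cluster entry, after gene 4, and at the primed→silenced
switch at gene 10), one weak border (an H3K27me3-only step around gene
7), and one moderate border (H3K27ac + H3K27me3 step down at the 5′ exit).
The fold columns show why each domain gets its label: the 3′ block is
accessible and actively marked with intermediate repression (primed),
while the 5′ block carries a 12-fold H3K27me3 load with baseline
accessibility (silenced).

The same pipeline is available from the shell:

```bash
trimark demo --seed 42 --outdir demo_run
# {"weak": 1, "moderate": 1, "strong": 3}
```

which writes bedGraph tracks, borders/domains BED files, per-cell
signal tables, insulation profiles and a JSON report. Other subcommands
(`simulate`, `qc`, `domains`, `cellstate`, `hic`, `network`, `diff`)
expose the individual stages on files.

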