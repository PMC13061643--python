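"""Synthetic multimodal chromatin data.

This module generates every input the analysis pipeline consumes, with the
statistical structure the method assumes: per-cell per-bin fragment counts
for three modalities (ATAC, H3K27ac, H3K27me3), a 13-gene HOX-like cluster
whose flanks and internal sub-segments realize inactive, primed and
silenced chromatin states with planted graded transitions, two cell
subgroups that differ only in 3' H3K27me3, contact matrices with distance
decay, single- vs split-TAD scenarios and planted loops, and directed
TF--TF edge lists with a configurable hub.

The planted HOX-like locus, 3' to 5' along coordinates:

========  =============  =====  ======  =======  ==========================
segment   content        ATAC   K27ac   K27me3   transition entering it
========  =============  =====  ======  =======  ==========================
s0        upstream flank 0.05   0.05    0.10     --
s1        genes 1-4      0.60   0.60    0.25     all three (strong)
s2        genes 5-6      0.40   0.40    0.40     all three (strong)
s3        genes 7-9      0.40   0.40    0.70     K27me3 only (weak)
s4        genes 10-13    0.05   0.05    1.20     all three (strong)
s5        downstream     0.05   0.20    0.30     K27ac + K27me3 (moderate)
========  =============  =====  ======  =======  ==========================

Rates are expected fragments per cell per 2-kb bin.  The magnitudes are
free parameters of the generator; only the ordinal relations (primed 3'
K27me3 above flanking chromatin and far below the 5' end) are structural.
A configurable fraction of "group 2" cells has its 3' (s1--s3) H3K27me3
rate reduced to the flanking level while H3K27ac is identical across
groups, so the two groups are distinguishable by H3K27me3 only.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .fragio import BinScheme, FragmentSet, write_fragments
from .hic import ContactMatrix

MODALITIES = ("atac", "k27ac", "k27me3")

#: (ATAC, H3K27ac, H3K27me3) expected fragments per cell per 2-kb bin.
SEGMENT_RATES: dict[str, tuple[float, float, float]] = {
    "s0": (0.05, 0.05, 0.10),
    "s1": (0.60, 0.60, 0.25),
    "s2": (0.40, 0.40, 0.40),
    "s3": (0.40, 0.40, 0.70),
    "s4": (0.05, 0.05, 1.20),
    "s5": (0.05, 0.20, 0.30),
}

#: Modalities whose rate steps at each inter-segment junction (grade truth).
TRANSITION_MODALITIES: dict[str, tuple[str, ...]] = {
    "s0/s1": ("atac", "k27ac", "k27me3"),
    "s1/s2": ("atac", "k27ac", "k27me3"),
    "s2/s3": ("k27me3",),
    "s3/s4": ("atac", "k27ac", "k27me3"),
    "s4/s5": ("k27ac", "k27me3"),
}


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Simulation parameters; a fixed seed gives byte-identical outputs."""

    seed: int = 0
    cells_per_type: int = 300
    n_cell_types: int = 3
    #: (subnucleosomal, mononucleosomal) fragment-length modes in bp.
    frag_len_modes: tuple[float, float] = (80.0, 200.0)
    frag_len_sds: tuple[float, float] = (15.0, 25.0)
    subnucleosomal_weight: float = 0.4
    noise: str = "poisson"            # "poisson" | "nb"
    nb_dispersion: float = 0.3
    group2_fraction: float = 0.3
    bin_width: int = 2_000
    chrom_length: int = 1_000_000
    #: differential-accessibility planting for the two-region comparison
    n_diff_bins: int = 50
    diff_fold: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.group2_fraction <= 1.0:
            raise ConfigurationError("group2_fraction must be in [0, 1]")
        if not 0.0 <= self.subnucleosomal_weight <= 1.0:
            raise ConfigurationError("subnucleosomal_weight must be in [0, 1]")
        if self.noise not in ("poisson", "nb"):
            raise ConfigurationError("noise must be 'poisson' or 'nb'")
        if self.noise == "nb" and self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.cells_per_type < 0:
            raise ConfigurationError("cells_per_type must be >= 0")
        if self.n_cell_types < 1:
            raise ConfigurationError("need at least one cell type")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per operation."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclasses.dataclass
class GeneModel:
    name: str
    tss: int
    strand: str = "+"


@dataclasses.dataclass
class ToyGenome:
    """Single-chromosome toy genome with a designated 13-gene cluster."""

    chrom: str
    length: int
    genes: list[GeneModel]
    cluster_genes: list[GeneModel]
    cluster_start: int
    cluster_end: int
    flank: int = 50_000
    #: coordinate intervals of the six planted segments, in order
    segments: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)
    marker_genes: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    @property
    def locus(self) -> tuple[int, int]:
        """The analyzed locus: cluster plus both flanks."""
        return self.cluster_start - self.flank, self.cluster_end + self.flank

    def segment_profiles(self) -> list["SegmentProfile"]:
        return [
            SegmentProfile(
                name=name, start=s, end=e,
                rates=dict(zip(MODALITIES, SEGMENT_RATES[name])),
            )
            for name, (s, e) in self.segments.items()
        ]


@dataclasses.dataclass
class SegmentProfile:
    """Planted per-modality mean fragment rate over one interval.

    Rates are expected fragments per cell per bin (``SimConfig.bin_width``).
    Segment intervals tile the fixture locus without overlap.
    """

    name: str
    start: int
    end: int
    rates: dict[str, float]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("segment rates must be non-negative")


def make_genome(config: SimConfig) -> ToyGenome:
    """Build the toy genome: one >=1 Mb chromosome, a 13-gene cluster
    spanning ~156 kb (one gene every 12 kb) and 20 background marker genes
    per simulated cell type placed away from the cluster."""
    w = config.bin_width
    length = config.chrom_length
    cluster_start = 400_000
    n_genes, gene_spacing = 13, 12_000
    cluster_span = n_genes * gene_spacing
    cluster_end = cluster_start + cluster_span
    flank = 50_000
    if cluster_end + flank > length or cluster_start - flank < 0:
        raise ConfigurationError("chromosome too short for the gene cluster")
    cluster_genes = [
        GeneModel(name=f"CLU{i + 1}", tss=cluster_start + 2_000 + i * gene_spacing)
        for i in range(n_genes)
    ]
    # gene-block edges define the planted segments, all bin-aligned (12 kb
    # spacing is a multiple of the 2 kb bin width)
    seg_edges = {
        "s0": (cluster_start - flank, cluster_start),
        "s1": (cluster_start, cluster_start + 4 * gene_spacing),
        "s2": (cluster_start + 4 * gene_spacing, cluster_start + 6 * gene_spacing),
        "s3": (cluster_start + 6 * gene_spacing, cluster_start + 9 * gene_spacing),
        "s4": (cluster_start + 9 * gene_spacing, cluster_end),
        "s5": (cluster_end, cluster_end + flank),
    }
    assert all(s % w == 0 and e % w == 0 for s, e in seg_edges.values())

    # background marker genes, clear of the locus
    marker_genes: dict[str, list[str]] = {}
    genes = list(cluster_genes)
    pos = 20_000
    for t in range(config.n_cell_types):
        names = []
        for g in range(20):
            name = f"MK{t}_{g}"
            genes.append(GeneModel(name=name, tss=pos, strand="+" if g % 2 else "-"))
            names.append(name)
            pos += 4_000
        marker_genes[f"type{t}"] = names
    if pos > cluster_start - flank - 10_000:
        raise ConfigurationError("too many marker genes for the chromosome")
    return ToyGenome(
        chrom="chrS", length=length, genes=genes, cluster_genes=cluster_genes,
        cluster_start=cluster_start, cluster_end=cluster_end, flank=flank,
        segments=seg_edges, marker_genes=marker_genes,
    )


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, rates: np.ndarray,
                 config: SimConfig) -> np.ndarray:
    """Per-(cell, bin) fragment counts under the configured noise model."""
    if config.noise == "poisson":
        return rng.poisson(rates)
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, np.maximum(rates, 0) / shape)
    return rng.poisson(lam)


def _fragment_lengths(rng: np.random.Generator, n: int,
                      config: SimConfig) -> np.ndarray:
    sub = rng.random(n) < config.subnucleosomal_weight
    lens = np.where(
        sub,
        rng.normal(config.frag_len_modes[0], config.frag_len_sds[0], n),
        rng.normal(config.frag_len_modes[1], config.frag_len_sds[1], n),
    )
    return np.maximum(np.round(lens).astype(np.int64), 20)


def _counts_to_fragments(
    rng: np.random.Generator,
    counts: np.ndarray,
    bin_starts: np.ndarray,
    barcodes: Sequence[str],
    chrom: str,
    chrom_length: int,
    config: SimConfig,
) -> FragmentSet:
    """Expand a (cells x bins) count matrix into fragment records.

    Each fragment's start is uniform within its bin; its length is drawn
    from the configured subnucleosomal/mononucleosomal mixture."""
    cell_idx, bin_idx = np.nonzero(counts)
    reps = counts[cell_idx, bin_idx]
    cell_idx = np.repeat(cell_idx, reps)
    bin_idx = np.repeat(bin_idx, reps)
    n = len(cell_idx)
    starts = bin_starts[bin_idx] + rng.integers(0, config.bin_width, n)
    ends = np.minimum(starts + _fragment_lengths(rng, n, config), chrom_length)
    starts = np.minimum(starts, ends - 20)  # keep start < end at the edge
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "barcode": np.asarray(barcodes)[cell_idx],
            "count": np.ones(n, dtype=np.int64),
        }
    )
    return FragmentSet(df).sorted()


# ---------------------------------------------------------------------------
# HOX-like fixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HoxFixture:
    """Fixture output: planted segment profiles, per-modality fragments,
    group labels and ground-truth transitions."""

    genome: ToyGenome
    profiles: list[SegmentProfile]
    fragments: dict[str, FragmentSet]
    barcodes: list[str]
    groups: pd.Series                      # barcode -> 1 | 2
    transitions: pd.DataFrame              # position, bin, modalities, grade
    config: SimConfig

    def truth_dict(self) -> dict:
        return {
            "locus": list(self.genome.locus),
            "bin_width": self.config.bin_width,
            "transitions": [
                {
                    "position": int(r.position),
                    "bin": int(r.bin),
                    "modalities": list(r.modalities),
                    "grade": int(r.grade),
                }
                for r in self.transitions.itertuples()
            ],
            "groups": {b: int(g) for b, g in self.groups.items()},
        }


def make_hox_fixture(genome: ToyGenome, config: SimConfig,
                     n_cells: int | None = None) -> HoxFixture:
    """Sample the three-modality HOX-like fixture.

    ``n_cells`` defaults to ``config.cells_per_type``.  Cells share one
    barcode space across modalities (the joint-profiling contract).  A
    ``config.group2_fraction`` subset of cells has its 3' (s1--s3)
    H3K27me3 rate reduced to the upstream-flank level; H3K27ac rates are
    identical across groups by construction.
    """
    if not genome.cluster_genes:
        raise ConfigurationError("genome has no designated cluster")
    n_cells = config.cells_per_type if n_cells is None else int(n_cells)
    w = config.bin_width
    locus_start, locus_end = genome.locus
    n_bins = (locus_end - locus_start) // w
    bin_starts = locus_start + np.arange(n_bins) * w
    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]

    rng = config.rng(1)
    n_group2 = int(round(config.group2_fraction * n_cells))
    group2 = np.zeros(n_cells, dtype=bool)
    if n_group2:
        group2[rng.choice(n_cells, size=n_group2, replace=False)] = True

    profiles = genome.segment_profiles()
    s0_k27me3 = SEGMENT_RATES["s0"][2]
    three_prime = {"s1", "s2", "s3"}

    fragments: dict[str, FragmentSet] = {}
    for m_i, modality in enumerate(MODALITIES):
        rates = np.zeros((n_cells, n_bins))
        for prof in profiles:
            lo = (prof.start - locus_start) // w
            hi = (prof.end - locus_start) // w
            rate = prof.rates[modality]
            rates[:, lo:hi] = rate
            if modality == "k27me3" and prof.name in three_prime:
                rates[group2, lo:hi] = s0_k27me3
        counts = _draw_counts(rng, rates, config)
        fragments[modality] = _counts_to_fragments(
            rng, counts, bin_starts, barcodes, genome.chrom,
            genome.length, config,
        )

    names = list(SEGMENT_RATES)
    rows = []
    for a, b in zip(names[:-1], names[1:]):
        pos = genome.segments[b][0]
        mods = TRANSITION_MODALITIES[f"{a}/{b}"]
        rows.append(
            {
                "position": pos,
                "bin": (pos - locus_start) // w,
                "modalities": tuple(mods),
                "grade": len(mods),
            }
        )
    transitions = pd.DataFrame(rows)
    groups = pd.Series(np.where(group2, 2, 1), index=barcodes, name="group")
    return HoxFixture(
        genome=genome, profiles=profiles, fragments=fragments,
        barcodes=barcodes, groups=groups, transitions=transitions,
        config=config,
    )


# ---------------------------------------------------------------------------
# multi-cell-type fragments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CellTypeSim:
    """Cell-type simulation output for annotation/differential stages."""

    genome: ToyGenome
    fragments: dict[str, FragmentSet]
    labels: pd.DataFrame        # barcode, cell_type, region
    scheme: BinScheme
    diff_bins: np.ndarray       # global bin ids planted as differential
    diff_fold: float
    config: SimConfig


#: background and marker promoter rates (fragments / cell / bin)
_BG_RATES = {"atac": 0.05, "k27ac": 0.05, "k27me3": 0.20}
_MARKER_OWN = {"atac": 0.80, "k27ac": 0.80, "k27me3": 0.02}
_MARKER_OTHER = {"atac": 0.05, "k27ac": 0.05, "k27me3": 0.40}


def simulate_celltype_fragments(genome: ToyGenome, config: SimConfig
                                ) -> CellTypeSim:
    """Simulate fragments for several cell types over the whole chromosome.

    Each cell type enriches its own marker-gene promoters in ATAC and
    H3K27ac and depletes them in H3K27me3 (other types carry the repressive
    mark there instead).  Within cell type 0, cells are split into two
    "regions" (R1/R2) and ``config.n_diff_bins`` background bins are
    planted as differentially accessible at ``config.diff_fold`` in R2.
    Zero configured cells yields empty fragment sets, not an error.
    """
    if config.n_cell_types < 2:
        raise ConfigurationError("need >= 2 cell types")
    w = config.bin_width
    scheme = BinScheme(width=w, chrom_sizes={genome.chrom: genome.length})
    n_bins = scheme.total_bins
    rng = config.rng(2)

    n_types = config.n_cell_types
    n_cells = config.cells_per_type * n_types
    barcodes = [f"CT{t}_{i:05d}" for t in range(n_types)
                for i in range(config.cells_per_type)]
    cell_type = np.repeat(np.arange(n_types), config.cells_per_type)
    region = np.array(["R1"] * n_cells, dtype=object)
    # two labeled regions within cell type 0, alternating for balance
    t0 = np.where(cell_type == 0)[0]
    region[t0[1::2]] = "R2"

    marker_bins = {
        t: np.unique(np.concatenate([
            np.arange(*scheme.region_bins(genome.chrom,
                                          max(g.tss - w, 0),
                                          min(g.tss + w, genome.length)))
            for g in genome.genes if g.name in genome.marker_genes[f"type{t}"]
        ]))
        for t in range(n_types)
    }
    all_marker = (np.concatenate(list(marker_bins.values()))
                  if marker_bins else np.array([], dtype=int))
    locus_lo, locus_hi = scheme.region_bins(genome.chrom, *genome.locus)
    forbidden = set(all_marker.tolist()) | set(range(locus_lo, locus_hi))
    candidates = np.array(sorted(set(range(n_bins)) - forbidden))
    diff_bins = np.sort(rng.choice(candidates, size=min(config.n_diff_bins,
                                                        len(candidates)),
                                   replace=False))

    fragments: dict[str, FragmentSet] = {}
    for modality in MODALITIES:
        rates = np.full((n_cells, n_bins), _BG_RATES[modality])
        for t in range(n_types):
            own = cell_type == t
            rates[np.ix_(own, marker_bins[t])] = _MARKER_OWN[modality]
            rates[np.ix_(~own, marker_bins[t])] = _MARKER_OTHER[modality]
        if modality == "atac" and len(diff_bins):
            r2 = region == "R2"
            rates[np.ix_(r2, diff_bins)] *= config.diff_fold
        counts = _draw_counts(rng, rates, config)
        fragments[modality] = _counts_to_fragments(
            rng, counts, scheme.bin_table()["start"].to_numpy(), barcodes,
            genome.chrom, genome.length, config,
        )
    labels = pd.DataFrame(
        {"barcode": barcodes,
         "cell_type": [f"type{t}" for t in cell_type],
         "region": region}
    )
    return CellTypeSim(genome=genome, fragments=fragments, labels=labels,
                       scheme=scheme, diff_bins=diff_bins,
                       diff_fold=config.diff_fold, config=config)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ContactSim:
    matrix: ContactMatrix
    scenario: str
    tads: list[tuple[int, int]]        # [lo, hi) bin intervals
    junction_bin: int | None
    loop_bins: list[tuple[int, int]]
    bin_width: int


def simulate_contact_matrix(
    scenario: str,
    loops: Sequence[tuple[tuple[int, int], tuple[int, int]]] = (),
    config: SimConfig | None = None,
    genome: ToyGenome | None = None,
    bin_width: int = 10_000,
    decay_scale: float = 200.0,
    tad_factor: float = 2.0,
    loop_factor: float = 3.0,
) -> ContactSim:
    """Simulate a symmetric binned contact matrix over the toy chromosome.

    Counts are Poisson around ``decay_scale / (1 + d)`` (``d`` the diagonal
    offset in bins), multiplied by ``tad_factor`` for within-TAD pixels and
    ``loop_factor`` at planted loop-anchor pixels.  ``single_tad`` places
    one insulated TAD over the cluster region; ``split_tad`` divides it at
    the mid-cluster border of the fixture (the primed/silenced junction).
    """
    if scenario not in ("single_tad", "split_tad"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    config = config or SimConfig()
    genome = genome or make_genome(config)
    rng = config.rng(3)
    n = genome.length // bin_width
    locus_lo, locus_hi = genome.locus
    tad_lo = (locus_lo - 20_000) // bin_width
    tad_hi = -(-(locus_hi + 20_000) // bin_width)
    junction_pos = genome.segments["s4"][0]         # mid-cluster strong border
    junction_bin = junction_pos // bin_width
    if scenario == "single_tad":
        tads = [(tad_lo, tad_hi)]
        junction = None
    else:
        tads = [(tad_lo, junction_bin), (junction_bin, tad_hi)]
        junction = junction_bin

    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.abs(i - j)
    expected = decay_scale / (1.0 + d)
    factor = np.ones((n, n))
    for lo, hi in tads:
        inside = (i >= lo) & (i < hi) & (j >= lo) & (j < hi)
        factor[inside] = tad_factor

    loop_bins: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in loops:
        b1 = (s1 + e1) // 2 // bin_width
        b2 = (s2 + e2) // 2 // bin_width
        if not (0 <= b1 < n and 0 <= b2 < n):
            raise ConfigurationError("loop anchor outside contact matrix")
        lo_b, hi_b = min(b1, b2), max(b1, b2)
        factor[lo_b, hi_b] *= loop_factor
        factor[hi_b, lo_b] = factor[lo_b, hi_b]
        loop_bins.append((lo_b, hi_b))

    lam = expected * factor
    upper = rng.poisson(np.triu(lam))
    counts = (upper + np.triu(upper, 1).T).astype(float)
    bins = pd.DataFrame(
        {"chrom": genome.chrom,
         "start": np.arange(n) * bin_width,
         "end": np.minimum(np.arange(1, n + 1) * bin_width, genome.length)}
    )
    cm = ContactMatrix(bins=bins, counts=counts)
    return ContactSim(matrix=cm, scenario=scenario, tads=tads,
                      junction_bin=junction, loop_bins=loop_bins,
                      bin_width=bin_width)


def default_loop_anchors(genome: ToyGenome,
                         bin_width: int = 10_000) -> list[tuple[tuple[int, int],
                                                                tuple[int, int]]]:
    """Two planted loops: one spanning the cluster, one in the background."""
    w = bin_width
    a = genome.cluster_start - 10_000
    b = genome.cluster_end + 10_000
    return [
        ((a, a + w), (b, b + w)),
        ((150_000, 150_000 + w), (300_000, 300_000 + w)),
    ]


# ---------------------------------------------------------------------------
# TF edge lists
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TFEdgeSim:
    edges: pd.DataFrame         # regulator, target
    propensities: np.ndarray
    out_degree: pd.Series
    in_degree: pd.Series


def simulate_tf_edges(
    n_tfs: int,
    config: SimConfig | None = None,
    propensities: Sequence[float] | None = None,
    base_prob: float = 0.15,
) -> TFEdgeSim:
    """Sample a directed TF--TF network without self-edges.

    The probability of an edge ``u -> v`` scales with the out-propensity of
    ``u`` (normalized to mean 1), so a TF with a 10x propensity is a hub.
    Ground-truth realized out-/in-degrees are recorded.
    """
    if n_tfs < 2:
        raise ConfigurationError("need at least 2 TFs")
    config = config or SimConfig()
    rng = config.rng(4)
    if propensities is None:
        props = np.ones(n_tfs)
    else:
        props = np.asarray(propensities, dtype=float)
        if len(props) != n_tfs or (props < 0).any():
            raise ConfigurationError("bad propensity vector")
    names = [f"TF{i:03d}" for i in range(n_tfs)]
    p = np.clip(base_prob * props / max(props.mean(), 1e-12), 0.0, 1.0)
    draw = rng.random((n_tfs, n_tfs)) < p[:, None]
    np.fill_diagonal(draw, False)
    reg_idx, tgt_idx = np.nonzero(draw)
    edges = pd.DataFrame(
        {"regulator": [names[i] for i in reg_idx],
         "target": [names[j] for j in tgt_idx]}
    )
    out_deg = pd.Series(draw.sum(axis=1), index=names, name="out_degree")
    in_deg = pd.Series(draw.sum(axis=0), index=names, name="in_degree")
    return TFEdgeSim(edges=edges, propensities=props,
                     out_degree=out_deg, in_degree=in_deg)


# ---------------------------------------------------------------------------
# on-disk truth
# ---------------------------------------------------------------------------

def write_fixture(fixture: HoxFixture, outdir: str | Path) -> dict[str, Path]:
    """Write fragments TSVs, segment/gene BEDs and the JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for modality, fs in fixture.fragments.items():
        p = outdir / f"fragments_{modality}.tsv"
        write_fragments(fs, p)
        paths[f"fragments_{modality}"] = p

    seg_bed = outdir / "segments.bed"
    with open(seg_bed, "w") as fh:
        fh.write("# planted segments (BED, 0-based half-open)\n")
        for prof in fixture.profiles:
            fh.write(f"{fixture.genome.chrom}\t{prof.start}\t{prof.end}"
                     f"\t{prof.name}\n")
    paths["segments"] = seg_bed

    gene_bed = outdir / "genes.bed"
    with open(gene_bed, "w") as fh:
        fh.write("# gene TSSs (BED6, 0-based half-open)\n")
        for g in fixture.genome.genes:
            fh.write(f"{fixture.genome.chrom}\t{g.tss}\t{g.tss + 1}"
                     f"\t{g.name}\t0\t{g.strand}\n")
    paths["genes"] = gene_bed

    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(fixture.truth_dict(), fh, indent=1)
    paths["truth"] = truth
    return paths
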