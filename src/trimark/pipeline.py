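"""End-to-end demonstration pipeline.

``run_demo`` executes simulate -> QC -> pseudobulk -> border/domain model
-> within-cell grouping -> contact-matrix analytics -> TF network ->
differential accessibility on fully synthetic data and writes a
structured JSON report plus human-readable tables.  Every stage is a thin
call into the library modules; the report captures all effective
parameters for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import cellstate, diffacc, domains, hic, networks, signal_qc, simulate
from .fragio import BinnedSignalTrack, BinScheme, bin_counts, write_bedgraph

log = logging.getLogger("trimark")


@dataclasses.dataclass
class PipelineConfig:
    """Schema-validated demo configuration; unknown keys are rejected."""

    seed: int = 42
    fixture_cells: int = 500
    celltype_cells: int = 300
    outdir: str = "trimark_demo"
    group2_fraction: float = 0.3
    noise: str = "poisson"
    border: domains.BorderParams = dataclasses.field(
        default_factory=domains.BorderParams)
    act_thresh: float = 2.0
    mid_thresh: float = 1.5
    high_thresh: float = 4.0
    insulation_window: int = 100_000
    contact_bin: int = 10_000
    n_perm: int = 2_000
    diff_alpha: float = 0.001
    diff_lfc: float = 1.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        border = raw.pop("border", None)
        cfg = cls(**raw)
        if border:
            cfg.border = domains.BorderParams(**border)
        return cfg

    def sim_config(self, cells: int) -> simulate.SimConfig:
        return simulate.SimConfig(
            seed=self.seed, cells_per_type=cells,
            group2_fraction=self.group2_fraction, noise=self.noise,
        )


def fixture_tracks(fixture: simulate.HoxFixture) -> dict:
    """Per-modality CPM pseudobulk tracks over the fixture locus."""
    genome = fixture.genome
    scheme = BinScheme(width=fixture.config.bin_width,
                       chrom_sizes={genome.chrom: genome.length})
    tracks = {}
    for mod, fs in fixture.fragments.items():
        mat, _ = bin_counts(fs, scheme, fixture.barcodes)
        tr = signal_qc.pseudobulk_track(
            mat, fixture.barcodes, {mod: fixture.barcodes}, scheme,
            region=(genome.chrom, *genome.locus))[mod]
        tracks[mod] = tr
    return tracks


def run_demo(config: PipelineConfig) -> dict:
    """Run the full demonstration and return the report dict.

    Raises ``RuntimeError`` if any stage's basic sanity property fails
    (e.g. no borders recovered), so callers can exit nonzero.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _param_dict(config)}

    # --- simulate -----------------------------------------------------
    log.info("simulating fixture (%d cells)", config.fixture_cells)
    sim_cfg = config.sim_config(config.fixture_cells)
    genome = simulate.make_genome(sim_cfg)
    fixture = simulate.make_hox_fixture(genome, sim_cfg)
    simulate.write_fixture(fixture, outdir / "fixture")

    # --- QC -----------------------------------------------------------
    tss = [g.tss for g in genome.cluster_genes]
    qc = signal_qc.tss_enrichment(fixture.fragments["atac"], tss)
    # thresholds scaled to simulated locus-level depth; sequencing-scale
    # defaults (TSSe > 7, > 3000 unique fragments) apply to real data
    retained, qc_report = signal_qc.qc_filter(qc, tsse_min=0.5, frag_min=10)
    qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    report["qc"] = {
        "n_cells": int(len(qc)),
        "median_tsse": float(qc["tss_enrichment"].median()),
        "median_fragments": float(qc["unique_fragments"].median()),
    }

    # --- pseudobulk + domain model ------------------------------------
    locus = genome.locus
    tracks = fixture_tracks(fixture)
    for mod, tr in tracks.items():
        write_bedgraph(tr, outdir / f"track_{mod}.bedgraph")

    model = domains.ChromatinDomainModel(
        tracks, params=config.border,
        baseline_interval=(locus[0], genome.cluster_start),
        act_thresh=config.act_thresh, mid_thresh=config.mid_thresh,
        high_thresh=config.high_thresh,
    )
    res = model.fit()
    if not res.borders:
        raise RuntimeError("domain stage failed: no borders recovered")
    _write_borders_bed(res, genome.chrom, outdir / "borders.bed")
    _write_domains_bed(res, genome.chrom, outdir / "domains.bed")
    report["borders"] = res.border_table().to_dict(orient="records")
    report["domains"] = res.domain_table().to_dict(orient="records")
    report["grade_counts"] = res.grade_counts()

    # --- within-cell grouping -----------------------------------------
    three_prime = (genome.segments["s1"][0], genome.segments["s3"][1])
    region = (genome.chrom, *three_prime)
    percell = cellstate.percell_region_signal(
        {m: fixture.fragments[m] for m in ("k27ac", "k27me3")},
        region, fixture.barcodes)
    split = cellstate.split_groups_by_mark(percell["norm_k27me3"])
    test = cellstate.test_mark_uniformity(
        percell["norm_k27ac"], split.labels, n_perm=config.n_perm,
        seed=config.seed)
    percell.assign(group=split.labels).to_csv(
        outdir / "percell_signal.tsv", sep="\t")
    report["cell_groups"] = {
        "split_ok": bool(split.ok),
        "silhouette": float(split.silhouette),
        "n_group1": int((split.labels == 1).sum()),
        "n_group2": int((split.labels == 2).sum()),
        "k27ac_uniformity_p": float(test.p_value),
        "k27ac_mean_diff": float(test.observed_diff),
    }

    # --- contact matrices ---------------------------------------------
    loops = simulate.default_loop_anchors(genome, config.contact_bin)
    hic_report = {}
    oe_by_scenario = {}
    for scenario in ("single_tad", "split_tad"):
        csim = simulate.simulate_contact_matrix(
            scenario, loops, sim_cfg, genome, bin_width=config.contact_bin)
        hic.ice_balance(csim.matrix)
        prof = hic.insulation(csim.matrix, window=config.insulation_window)
        oe_by_scenario[scenario] = hic.obs_exp(csim.matrix)
        cluster_bins = (genome.cluster_start // config.contact_bin,
                        genome.cluster_end // config.contact_bin)
        internal = prof.boundaries[
            (prof.boundaries["bin"] > cluster_bins[0] + 1)
            & (prof.boundaries["bin"] < cluster_bins[1] - 1)]
        hic_report[scenario] = {
            "n_internal_boundaries": int(len(internal)),
            "internal_bins": internal["bin"].tolist(),
            "junction_bin": csim.junction_bin,
        }
        track = BinnedSignalTrack(
            chrom=genome.chrom, start=0, width=config.contact_bin,
            values=np.nan_to_num(prof.scores),
            normalization="raw", label=f"insulation_{scenario}")
        write_bedgraph(track, outdir / f"insulation_{scenario}.bedgraph")
        csim_loop_bins = csim.loop_bins
    pileup = hic.loop_pileup(oe_by_scenario["single_tad"], csim_loop_bins)
    report["hic"] = hic_report
    report["hic"]["loop_pileup_enrichment"] = float(pileup.enrichment)

    # --- TF network -----------------------------------------------------
    props = np.ones(30)
    props[0] = 10.0
    tf_sim = simulate.simulate_tf_edges(30, sim_cfg, propensities=props)
    net = networks.TFNetwork.from_edges(
        zip(tf_sim.edges["regulator"], tf_sim.edges["target"]))
    strengths = networks.tf_strength(net)
    ranked = networks.rank_tfs(strengths)
    ranked.to_csv(outdir / "tf_ranked.tsv", sep="\t", index=False)
    report["network"] = {
        "n_tfs": int(len(strengths)),
        "n_edges": int(len(net.edges)),
        "strength_sum": int(strengths.sum()),
        "top_tf": str(ranked["tf"].iloc[0]),
    }

    # --- differential accessibility -------------------------------------
    ct_cfg = config.sim_config(config.celltype_cells)
    ct = simulate.simulate_celltype_fragments(genome, ct_cfg)
    mat, _ = bin_counts(ct.fragments["atac"], ct.scheme,
                        ct.labels["barcode"].tolist())
    t0 = ct.labels["cell_type"] == "type0"
    group_a = ct.labels.loc[t0 & (ct.labels["region"] == "R2"),
                            "barcode"].tolist()
    group_b = ct.labels.loc[t0 & (ct.labels["region"] == "R1"),
                            "barcode"].tolist()
    diff = diffacc.differential_accessibility(
        mat, ct.labels["barcode"].tolist(), group_a, group_b,
        alpha=config.diff_alpha, lfc_min=config.diff_lfc)
    sig = diff[diff["significant"]]
    planted = set(ct.diff_bins.tolist())
    report["differential"] = {
        "n_tested": int(len(diff)),
        "n_significant": int(len(sig)),
        "n_planted": len(planted),
        "planted_recovered": int(sig["feature"].isin(planted).sum()),
    }
    diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(res.summary() + "\n\n")
        fh.write(json.dumps(report, indent=1, default=_jsonable))
    return report


def _param_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _write_borders_bed(res: domains.DomainResults, chrom: str,
                       path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# graded borders (BED, 0-based half-open); "
                 "name=grade, score=modality count x 333 capped at 999\n")
        for b in res.borders:
            score = min(b.grade * 333, 999)
            fh.write(f"{chrom}\t{b.position}\t{b.position + 1}"
                     f"\t{b.grade_name}\t{score}\n")


def _write_domains_bed(res: domains.DomainResults, chrom: str,
                       path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chromatin domains (BED, 0-based half-open); name=state\n")
        for d in res.domains:
            fh.write(f"{chrom}\t{d.start}\t{d.end}\t{d.state}\n")
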