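import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trimark as tm
from trimark import simulate
from trimark.simulate import (SEGMENT_RATES, TRANSITION_MODALITIES,
                              ConfigurationError)

from oracles import diamond_sums_bruteforce


class TestMakeGenome:
    def test_cluster_genes_in_coordinate_order(self, genome):
        tss = [g.tss for g in genome.cluster_genes]
        assert len(tss) == 13
        assert tss == sorted(tss)

    def test_segments_tile_locus(self, genome):
        segs = list(genome.segments.values())
        assert segs[0][0] == genome.locus[0]
        assert segs[-1][1] == genome.locus[1]
        for (s0, e0), (s1, e1) in zip(segs[:-1], segs[1:]):
            assert e0 == s1

    def test_marker_genes_per_type(self, genome, sim_config):
        assert len(genome.marker_genes) == sim_config.n_cell_types
        assert all(len(v) == 20 for v in genome.marker_genes.values())

    def test_determinism(self, sim_config):
        g1 = tm.make_genome(sim_config)
        g2 = tm.make_genome(sim_config)
        assert [g.tss for g in g1.genes] == [g.tss for g in g2.genes]

    def test_chromosome_too_short(self):
        with pytest.raises(ConfigurationError):
            tm.make_genome(tm.SimConfig(chrom_length=200_000))


class TestHoxFixture:
    def test_deterministic_fragments(self, genome):
        cfg = tm.SimConfig(seed=5, cells_per_type=50)
        a = tm.make_hox_fixture(genome, cfg)
        b = tm.make_hox_fixture(genome, cfg)
        for m in a.fragments:
            pd.testing.assert_frame_equal(a.fragments[m].df,
                                          b.fragments[m].df)

    def test_transition_truth_consistent_with_rate_table(self, hox_fixture):
        """Planted grades: 3 three-modality, 1 two-, 1 one-modality, and
        membership agrees with which rates actually step at each junction."""
        names = list(SEGMENT_RATES)
        grades = sorted(hox_fixture.transitions["grade"])
        assert grades == [1, 2, 3, 3, 3]
        for (a, b), row in zip(zip(names[:-1], names[1:]),
                               hox_fixture.transitions.itertuples()):
            changed = tuple(
                m for m, ra, rb in zip(("atac", "k27ac", "k27me3"),
                                       SEGMENT_RATES[a], SEGMENT_RATES[b])
                if ra != rb)
            assert changed == TRANSITION_MODALITIES[f"{a}/{b}"]
            assert set(row.modalities) == set(changed)

    def test_segment_means_within_3se(self, genome):
        """Empirical per-segment fragment rates match configured rates."""
        n = 500
        cfg = tm.SimConfig(seed=11, cells_per_type=n, group2_fraction=0.0)
        fx = tm.make_hox_fixture(genome, cfg)
        w = cfg.bin_width
        for m_i, m in enumerate(("atac", "k27ac", "k27me3")):
            df = fx.fragments[m].df
            for prof in fx.profiles:
                n_bins = (prof.end - prof.start) // w
                hit = (df["start"] >= prof.start) & (df["start"] < prof.end)
                mean = df.loc[hit, "count"].sum() / (n * n_bins)
                rate = prof.rates[m]
                se = np.sqrt(rate / (n * n_bins))
                assert abs(mean - rate) < 3 * se + 1e-12, (m, prof.name)

    def test_group2_fraction_zero_single_profile(self, genome):
        cfg = tm.SimConfig(seed=3, cells_per_type=40, group2_fraction=0.0)
        fx = tm.make_hox_fixture(genome, cfg)
        assert (fx.groups == 1).all()

    def test_group2_k27me3_depleted_k27ac_matched(self, genome):
        """Group 2 cells lose 3' H3K27me3 down to the flanking level while
        H3K27ac stays identical across groups by construction."""
        cfg = tm.SimConfig(seed=13, cells_per_type=400, group2_fraction=0.5)
        fx = tm.make_hox_fixture(genome, cfg)
        lo = genome.segments["s1"][0]
        hi = genome.segments["s3"][1]
        means = {}
        for m in ("k27ac", "k27me3"):
            df = fx.fragments[m].df
            hit = df[(df["start"] >= lo) & (df["start"] < hi)]
            per_cell = hit.groupby("barcode")["count"].sum() \
                .reindex(fx.barcodes, fill_value=0)
            means[m] = {g: per_cell[fx.groups == g].mean() for g in (1, 2)}
        assert means["k27me3"][1] > 2 * means["k27me3"][2]
        # H3K27ac exchangeable: two-sample t should not reject strongly
        assert abs(means["k27ac"][1] - means["k27ac"][2]) \
            < 0.2 * means["k27ac"][1]

    def test_k27ac_exchangeability_over_seeds(self, genome):
        """KS p-values comparing group H3K27ac distributions stay
        non-degenerate across seeds (equal by construction)."""
        lo = genome.segments["s1"][0]
        hi = genome.segments["s3"][1]
        pvals = []
        for seed in range(10):
            cfg = tm.SimConfig(seed=seed, cells_per_type=150,
                               group2_fraction=0.4)
            fx = tm.make_hox_fixture(genome, cfg)
            df = fx.fragments["k27ac"].df
            hit = df[(df["start"] >= lo) & (df["start"] < hi)]
            per_cell = hit.groupby("barcode")["count"].sum() \
                .reindex(fx.barcodes, fill_value=0)
            p = stats.ks_2samp(per_cell[fx.groups == 1],
                               per_cell[fx.groups == 2]).pvalue
            pvals.append(p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_rate_convergence_at_depth(self, genome):
        """Per-segment empirical rates within 5% relative at 2000 cells."""
        cfg = tm.SimConfig(seed=17, cells_per_type=2000, group2_fraction=0.0)
        fx = tm.make_hox_fixture(genome, cfg)
        w = cfg.bin_width
        df = fx.fragments["k27me3"].df
        for prof in fx.profiles:
            n_bins = (prof.end - prof.start) // w
            hit = (df["start"] >= prof.start) & (df["start"] < prof.end)
            mean = df.loc[hit, "count"].sum() / (2000 * n_bins)
            assert abs(mean / prof.rates["k27me3"] - 1) < 0.05

    def test_fragment_length_mixture(self, hox_fixture):
        lens = (hox_fixture.fragments["atac"].df["end"]
                - hox_fixture.fragments["atac"].df["start"])
        # two modes around 80 and 200 bp
        assert 60 < lens[lens < 140].mean() < 100
        assert 180 < lens[lens >= 140].mean() < 220


@pytest.fixture(scope="module")
def ct():
    cfg = tm.SimConfig(seed=21, cells_per_type=300, n_cell_types=3)
    genome = tm.make_genome(cfg)
    return tm.simulate_celltype_fragments(genome, cfg)


class TestCellTypeSim:
    def test_marker_enrichment_own_type(self, ct, genome):
        scheme = ct.scheme
        mat, _ = tm.bin_counts(ct.fragments["atac"], scheme,
                               ct.labels["barcode"].tolist())
        genes = {g.name: g for g in genome.genes}
        for t in ("type0", "type1", "type2"):
            bins = np.unique(np.concatenate([
                np.arange(*scheme.region_bins(genome.chrom,
                                              genes[n].tss - 2000,
                                              genes[n].tss + 2000))
                for n in genome.marker_genes[t]]))
            own = (ct.labels["cell_type"] == t).to_numpy()
            own_mean = mat[own][:, bins].mean()
            other_mean = mat[~own][:, bins].mean()
            assert own_mean > 2 * other_mean

    def test_differential_bins_sign(self, ct):
        """Planted 3-fold bins show the correct pseudobulk fold-change
        direction in >= 45/50 bins."""
        mat, _ = tm.bin_counts(ct.fragments["atac"], ct.scheme,
                               ct.labels["barcode"].tolist())
        t0 = ct.labels["cell_type"] == "type0"
        r2 = (t0 & (ct.labels["region"] == "R2")).to_numpy()
        r1 = (t0 & (ct.labels["region"] == "R1")).to_numpy()
        up = 0
        for b in ct.diff_bins:
            if mat[r2][:, b].mean() > mat[r1][:, b].mean():
                up += 1
        assert up >= 45

    def test_zero_cells_empty_not_error(self, genome):
        cfg = tm.SimConfig(seed=1, cells_per_type=0)
        out = tm.simulate_celltype_fragments(genome, cfg)
        assert all(len(fs) == 0 for fs in out.fragments.values())

    def test_determinism_barcode_count_tables(self, genome):
        cfg = tm.SimConfig(seed=9, cells_per_type=50)
        a = tm.simulate_celltype_fragments(genome, cfg)
        b = tm.simulate_celltype_fragments(genome, cfg)
        for m in a.fragments:
            pd.testing.assert_series_equal(
                a.fragments[m].per_barcode_counts(),
                b.fragments[m].per_barcode_counts())


class TestContactSim:
    def test_symmetric_exact(self, genome, sim_config):
        sim = tm.simulate_contact_matrix("single_tad", [], sim_config, genome)
        np.testing.assert_array_equal(sim.matrix.counts, sim.matrix.counts.T)

    def test_within_vs_cross_tad_enrichment(self, genome, sim_config):
        """Distance-matched raw counts are >= 1.5x enriched within the TAD
        (planted factor 2; ICE balancing would absorb part of a block
        enrichment, so the generator invariant is checked pre-balancing)."""
        sim = tm.simulate_contact_matrix("single_tad", [], sim_config, genome)
        counts = sim.matrix.counts
        lo, hi = sim.tads[0]
        n = counts.shape[0]
        within, cross = [], []
        for d in range(3, hi - lo):
            i = np.arange(n - d)
            j = i + d
            diag = counts[i, j]
            inside = (i >= lo) & (j < hi)
            outside = (j < lo) | (i >= hi)
            within.append(diag[inside].mean())
            cross.append(diag[outside].mean())
        assert np.mean(np.array(within) / np.array(cross)) > 1.5

    def test_single_tad_no_internal_insulation_minimum(self, genome,
                                                       sim_config):
        """Oracle insulation scan finds no diamond-sum minimum inside the
        cluster for the single-TAD scenario."""
        sim = tm.simulate_contact_matrix("single_tad", [], sim_config, genome)
        tm.ice_balance(sim.matrix)
        sums = diamond_sums_bruteforce(sim.matrix.balanced(), 10)
        lo = genome.cluster_start // 10_000 + 2
        hi = genome.cluster_end // 10_000 - 2
        inside = sums[lo:hi]
        # log-ratio dips inside the cluster stay shallow (no junction)
        assert np.nanmin(inside) > 0.7 * np.nanmedian(inside)

    def test_split_tad_junction_is_minimum(self, genome, sim_config):
        sim = tm.simulate_contact_matrix("split_tad", [], sim_config, genome)
        tm.ice_balance(sim.matrix)
        sums = diamond_sums_bruteforce(sim.matrix.balanced(), 10)
        lo = genome.cluster_start // 10_000 + 2
        hi = genome.cluster_end // 10_000 - 2
        argmin = lo + int(np.nanargmin(sums[lo:hi]))
        assert abs(argmin - sim.junction_bin) <= 1

    def test_loop_anchor_outside_matrix_error(self, genome, sim_config):
        with pytest.raises(ConfigurationError):
            tm.simulate_contact_matrix(
                "single_tad", [((0, 10_000), (2_000_000, 2_010_000))],
                sim_config, genome)

    def test_unknown_scenario(self, sim_config):
        with pytest.raises(ConfigurationError):
            tm.simulate_contact_matrix("three_tads", [], sim_config)


class TestTFEdgeSim:
    def test_hub_has_max_out_degree(self):
        wins = 0
        for seed in range(100):
            props = np.ones(20)
            props[3] = 10.0
            sim = tm.simulate_tf_edges(
                20, tm.SimConfig(seed=seed), propensities=props)
            if sim.out_degree.idxmax() == "TF003":
                wins += 1
        assert wins >= 95

    def test_zero_propensity_no_edges(self):
        sim = tm.simulate_tf_edges(5, tm.SimConfig(seed=0),
                                   propensities=[0] * 5)
        assert len(sim.edges) == 0

    def test_no_self_edges(self):
        sim = tm.simulate_tf_edges(15, tm.SimConfig(seed=2), base_prob=0.9)
        assert (sim.edges["regulator"] != sim.edges["target"]).all()

    def test_degree_truth_matches_edges(self):
        sim = tm.simulate_tf_edges(10, tm.SimConfig(seed=4))
        out = sim.edges.groupby("regulator").size()
        for tf, d in out.items():
            assert sim.out_degree[tf] == d
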