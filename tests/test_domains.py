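import dataclasses

import numpy as np
import pandas as pd
import pytest

import trimark as tm
from trimark import domains, pipeline
from trimark.domains import (BorderParams, ModalityBoundary,
                             aggregate_boundaries, classify_domains,
                             detect_boundaries)

from oracles import pearson


def track(values, width=2000, start=0):
    return tm.BinnedSignalTrack("chrS", start, width, np.asarray(values,
                                                                 dtype=float))


def flat_tracks(n=60, atac=1.0, k27ac=1.0, k27me3=1.0):
    return {"atac": track(np.full(n, atac)),
            "k27ac": track(np.full(n, k27ac)),
            "k27me3": track(np.full(n, k27me3))}


class TestDetectBoundaries:
    def test_constant_track_no_boundaries(self):
        assert detect_boundaries(track(np.full(50, 4.2)), BorderParams()) == []

    def test_single_step_localized(self, rng):
        """A clean step at bin b yields exactly one boundary within one bin
        of b, for every step position away from the edges."""
        params = BorderParams()
        for b in (15, 25, 40):
            v = np.where(np.arange(60) < b, 1.0, 5.0)
            v = v + rng.normal(0, 0.01, 60)
            out = detect_boundaries(track(v), params)
            assert len(out) == 1
            assert abs(out[0].bin - b) <= 1
            assert out[0].direction == "up"

    def test_noise_free_step(self):
        v = np.where(np.arange(40) < 20, 2.0, 1.0)
        out = detect_boundaries(track(v), BorderParams())
        assert len(out) == 1 and out[0].direction == "down"

    def test_two_equal_steps_merge_to_leftmost(self):
        v = np.concatenate([np.zeros(20), [1.0], np.full(19, 2.0)])
        params = BorderParams(sigma=0.5, min_separation=2)
        out = detect_boundaries(track(v), params)
        assert len(out) == 1
        assert out[0].bin == 20  # leftmost of the tie

    def test_short_track_error(self):
        with pytest.raises(ValueError):
            detect_boundaries(track([1.0, 2.0]), BorderParams())


class TestAggregateBoundaries:
    def mb(self, mod, b, z=10.0):
        return ModalityBoundary(modality=mod, bin=b, position=b * 2000,
                                direction="up", z=z)

    def test_three_coincident_strong(self):
        borders = aggregate_boundaries(
            {m: [self.mb(m, 10)] for m in ("atac", "k27ac", "k27me3")})
        assert len(borders) == 1
        assert borders[0].grade == 3 and borders[0].grade_name == "strong"

    def test_two_within_tolerance_moderate(self):
        borders = aggregate_boundaries(
            {"atac": [self.mb("atac", 10)], "k27ac": [self.mb("k27ac", 12)],
             "k27me3": []}, tolerance_bins=2)
        assert len(borders) == 1 and borders[0].grade_name == "moderate"
        assert borders[0].bin == 11

    def test_single_modality_weak(self):
        borders = aggregate_boundaries({"k27me3": [self.mb("k27me3", 5)]})
        assert borders[0].grade == 1 and borders[0].grade_name == "weak"

    def test_beyond_tolerance_separate_borders(self):
        borders = aggregate_boundaries(
            {"atac": [self.mb("atac", 10)], "k27ac": [self.mb("k27ac", 16)]},
            tolerance_bins=2)
        assert len(borders) == 2
        assert all(b.grade == 1 for b in borders)

    def test_modality_contributes_once_keeping_largest_z(self):
        borders = aggregate_boundaries(
            {"atac": [self.mb("atac", 10, z=3.0), self.mb("atac", 11, z=9.0)],
             "k27ac": [self.mb("k27ac", 10, z=5.0)]})
        assert len(borders) == 1
        b = borders[0]
        assert b.grade == 2
        kept_atac = [m for m in b.members if m.modality == "atac"][0]
        assert kept_atac.z == 9.0

    def test_order_invariance(self):
        pm = {"atac": [self.mb("atac", 10)], "k27ac": [self.mb("k27ac", 11)],
              "k27me3": [self.mb("k27me3", 30)]}
        a = aggregate_boundaries(pm)
        b = aggregate_boundaries(dict(reversed(list(pm.items()))))
        assert [(x.bin, x.grade) for x in a] == [(x.bin, x.grade) for x in b]


class TestClassifyDomains:
    def borders_at(self, positions):
        return [domains.GradedBorder(position=p, bin=p // 2000,
                                     modalities=frozenset({"atac"}),
                                     grade=1, members=[]) for p in positions]

    def test_all_zero_segment_is_inactive(self):
        tracks = flat_tracks(60)
        for m in tracks:
            tracks[m].values[30:] = 0.0
        out = classify_domains(self.borders_at([60_000]), tracks,
                               baseline_interval=(0, 40_000))
        assert out[1].state == "inactive"

    def test_rule_evaluation_silenced(self):
        tracks = flat_tracks(60)
        tracks["k27me3"].values[30:] = 10.0
        tracks["atac"].values[30:] = 0.5
        out = classify_domains(self.borders_at([60_000]), tracks,
                               baseline_interval=(0, 40_000))
        assert out[1].state == "silenced"

    def test_rule_evaluation_primed(self):
        tracks = flat_tracks(60)
        for m, v in (("atac", 5.0), ("k27ac", 5.0), ("k27me3", 2.0)):
            tracks[m].values[30:] = v
        out = classify_domains(self.borders_at([60_000]), tracks,
                               baseline_interval=(0, 40_000))
        assert out[1].state == "primed"

    def test_zero_baseline_error_mentions_pseudocount(self):
        tracks = flat_tracks(60)
        tracks["k27ac"].values[:20] = 0.0
        with pytest.raises(ValueError, match="pseudocount"):
            classify_domains([], tracks, baseline_interval=(0, 40_000))

    def test_domains_tile_locus(self):
        tracks = flat_tracks(60)
        out = classify_domains(self.borders_at([20_000, 80_000]), tracks,
                               baseline_interval=(0, 20_000))
        assert out[0].start == 0 and out[-1].end == 120_000
        for a, b in zip(out[:-1], out[1:]):
            assert a.end == b.start


@pytest.fixture(scope="module")
def fitted(hox_tracks, genome):
    model = domains.ChromatinDomainModel(
        hox_tracks, baseline_interval=(genome.locus[0],
                                       genome.cluster_start))
    return model.fit()


class TestModelOnFixture:

    def test_macro_states_inactive_primed_silenced(self, fitted, genome):
        by_segment = {}
        for name, (s, e) in genome.segments.items():
            mid = (s + e) // 2
            for d in fitted.domains:
                if d.start <= mid < d.end:
                    by_segment[name] = d.state
        assert by_segment["s0"] == "inactive"
        assert by_segment["s1"] == by_segment["s2"] == by_segment["s3"] \
            == "primed"
        assert by_segment["s4"] == "silenced"

    def test_grade_invariant_to_track_rescaling(self, hox_tracks, genome):
        scaled = dict(hox_tracks)
        scaled["k27me3"] = dataclasses.replace(
            hox_tracks["k27me3"], values=hox_tracks["k27me3"].values * 37.0)
        base = domains.ChromatinDomainModel(
            hox_tracks, baseline_interval=(genome.locus[0],
                                           genome.cluster_start)).fit()
        resc = domains.ChromatinDomainModel(
            scaled, baseline_interval=(genome.locus[0],
                                       genome.cluster_start)).fit()
        assert [(b.bin, b.grade) for b in base.borders] \
            == [(b.bin, b.grade) for b in resc.borders]

    def test_grade_monotone_in_depth(self, genome):
        """More cells never lower the recovered grade of a planted border."""
        grades_by_depth = []
        for cells in (200, 500, 1000):
            cfg = tm.SimConfig(seed=3, cells_per_type=cells)
            fx = tm.make_hox_fixture(genome, cfg)
            res = domains.ChromatinDomainModel(
                pipeline.fixture_tracks(fx),
                baseline_interval=(genome.locus[0],
                                   genome.cluster_start)).fit()
            grades = {}
            for t in fx.transitions.itertuples():
                near = [b.grade for b in res.borders
                        if abs(b.bin - t.bin) <= 2]
                grades[t.bin] = max(near) if near else 0
            grades_by_depth.append(grades)
        for lo, hi in zip(grades_by_depth[:-1], grades_by_depth[1:]):
            for b in lo:
                assert hi[b] >= lo[b]

    def test_summary_mentions_borders_and_domains(self, fitted):
        text = fitted.summary()
        assert "Borders" in text and "Domains" in text
        assert "primed" in text


class TestTrimodalCluster:
    def test_duplicated_column_zero_cophenetic(self, rng):
        x = rng.normal(0, 1, (20, 3))
        df = pd.DataFrame(np.hstack([x, x[:, [0]]]),
                          columns=["a", "b", "c", "a2"])
        out = tm.trimodal_cluster(df)
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import pdist, squareform
        coph = squareform(cophenet(out.col_linkage,
                                   pdist(df.to_numpy().T))[1])
        # identical columns 'a' and 'a2' share identical row-scaled profiles
        assert coph[0, 3] == 0.0

    def test_planted_two_block_recovery(self, rng):
        block1 = rng.normal([5, 5, 0, 0], 0.2, (15, 4))
        block2 = rng.normal([0, 0, 5, 5], 0.2, (15, 4))
        df = pd.DataFrame(np.vstack([block1, block2]))
        out = tm.trimodal_cluster(df)
        labels = out.cut_rows(2)
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_leaf_order_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (12, 5)))
        a = tm.trimodal_cluster(df)
        b = tm.trimodal_cluster(df)
        np.testing.assert_array_equal(a.row_leaves, b.row_leaves)
        np.testing.assert_array_equal(a.col_leaves, b.col_leaves)


class TestModalityCorrelation:
    def test_unit_diagonal_symmetric(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (30, 4)))
        corr = tm.modality_correlation(df)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_antiphased_profiles_negative(self, rng):
        base = rng.gamma(2.0, 1.0, 50)
        df = pd.DataFrame({"atac": base + rng.normal(0, 0.05, 50),
                           "k27me3": base.max() - base
                           + rng.normal(0, 0.05, 50)})
        corr = tm.modality_correlation(df)
        assert corr.loc["atac", "k27me3"] < -0.9

    def test_matches_textbook_formula(self, rng):
        df = pd.DataFrame(rng.normal(0, 2, (40, 3)), columns=list("xyz"))
        corr = tm.modality_correlation(df)
        for a in "xyz":
            for b in "xyz":
                assert corr.loc[a, b] == pytest.approx(
                    pearson(df[a], df[b]), rel=1e-12)
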