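import numpy as np
import pandas as pd
import pytest

from sucrophylo import cnv, synth
from sucrophylo.cnv import CNVMatrix, CoverageTrack, FeatureDef
from sucrophylo.genome import Genome

from oracles import mann_whitney_exact_two_sided


class TestProbeReference:
    SOURCE = Genome("ref", [("chrI", "ACGT" * 1_000)])

    def test_probe_length_arithmetic(self):
        f = FeatureDef("gene1", "chrI", 1_000, 1_900, flank_up=500, flank_down=500)
        probe, cmap = cnv.build_probe_reference([f], self.SOURCE)
        assert len(probe.contigs[0][1]) == 1_900
        assert probe.contigs[0][0] == "gene1"

    def test_short_flank_rejected_without_override(self):
        f = FeatureDef("gene1", "chrI", 1_000, 1_900, flank_up=200, flank_down=500)
        with pytest.raises(ValueError, match="gene1"):
            cnv.build_probe_reference([f], self.SOURCE)
        probe, _ = cnv.build_probe_reference([f], self.SOURCE, allow_short_flanks=True)
        assert len(probe.contigs[0][1]) == 1_600

    def test_coordinate_map_bijects_to_source(self):
        f = FeatureDef("g", "chrI", 1_000, 1_300, flank_up=250, flank_down=250)
        probe, cmap = cnv.build_probe_reference([f], self.SOURCE)
        coords = cmap["g"]
        assert len(coords) == len(probe.contigs[0][1])
        assert len(set(coords)) == len(coords)  # unique source bases
        src = self.SOURCE.contigs[0][1]
        for probe_pos, (seq, src_pos) in enumerate(coords):
            assert probe.contigs[0][1][probe_pos] == src[src_pos]


class TestNormalizedCopyNumber:
    def test_flat_coverage_gives_one(self):
        track = CoverageTrack({"c": np.full(10_000, 42)})
        f = FeatureDef("f", "c", 2_000, 4_000)
        assert cnv.normalized_copy_number(track, f) == pytest.approx(1.0)

    def test_threefold_feature_depth(self):
        depth = np.full(10_000, 50)
        depth[2_000:4_000] = 150
        # background includes the feature: mean = (8000*50+2000*150)/10000 = 70
        track = CoverageTrack({"c": depth})
        f = FeatureDef("f", "c", 2_000, 4_000)
        assert cnv.normalized_copy_number(track, f) == pytest.approx(150 / 70)

    def test_scale_invariance_under_deterministic_depth_scaling(self):
        rng = np.random.default_rng(8)
        depth = rng.poisson(30, size=5_000)
        f = FeatureDef("f", "c", 1_000, 2_000)
        base = cnv.normalized_copy_number(CoverageTrack({"c": depth}), f)
        scaled = cnv.normalized_copy_number(CoverageTrack({"c": depth * 7}), f)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_recovers_simulated_copies(self):
        """True copies {0,1,2,3,7} at λ=50 over 2 kb features within ±0.1.

        The features occupy 0.25% of a 4 Mb genome, so the genome-wide mean
        used as background is essentially the single-copy depth (as in real
        data, where probed regions are a negligible genome fraction)."""
        copies = [0.0, 1.0, 2.0, 3.0, 7.0]
        features = [
            FeatureDef(f"f{c:g}", "chr1", 100_000 + i * 50_000,
                       102_000 + i * 50_000, reference_copies=c)
            for i, c in enumerate(copies)
        ]
        track, truth = synth.simulate_coverage(features, 4_000_000, 50.0, seed=20)
        for f in features:
            est = cnv.normalized_copy_number(track, f)
            assert est == pytest.approx(truth.copy_numbers[f.feature_id], abs=0.1)

    def test_errors(self):
        track = CoverageTrack({"c": np.full(100, 10)})
        with pytest.raises(ValueError, match="not covered"):
            cnv.normalized_copy_number(track, FeatureDef("f", "other", 0, 10))
        with pytest.raises(ValueError, match="past coverage"):
            cnv.normalized_copy_number(track, FeatureDef("f", "c", 50, 200))


class TestDifferentialCNV:
    FEATURES = [
        FeatureDef("a", "c", 0, 10, reference_copies=1.0),
        FeatureDef("b", "c", 20, 30, reference_copies=2.0),
    ]

    def test_zero_when_estimates_equal_reference(self):
        est = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["s1", "s2"])
        m = cnv.differential_cnv(est, self.FEATURES)
        assert (m.values.values == 0).all()

    def test_signed_differential(self):
        est = pd.DataFrame({"a": [1.0], "b": [5.6]}, index=["s1"])
        m = cnv.differential_cnv(est, self.FEATURES)
        assert m.values.loc["s1", "b"] == pytest.approx(3.6)

    def test_heatmap_clips_display_but_keeps_raw_values(self):
        est = pd.DataFrame({"a": [1.0], "b": [7.6]}, index=["s1"])
        m = cnv.differential_cnv(est, self.FEATURES)
        assert m.values.loc["s1", "b"] == pytest.approx(5.6)  # raw retained
        assert m.heatmap_classes().loc["s1", "b"] == pytest.approx(4.0)
        assert bool(m.over_clip_mask().loc["s1", "b"]) is True

    def test_tsv_roundtrip(self, tmp_path):
        est = pd.DataFrame({"a": [0.5], "b": [2.5]}, index=["s1"])
        m = cnv.differential_cnv(est, self.FEATURES)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        pd.testing.assert_frame_equal(back, m.values, check_names=False)


class TestMannWhitney:
    def test_hand_example_exact(self):
        u, p = cnv.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        # perfectly interleaved identical values -> no separation
        _, p = cnv.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_u_plus_uprime_identity(self):
        rng = np.random.default_rng(30)
        x, y = rng.normal(size=5), rng.normal(size=4)
        ux, _ = cnv.mann_whitney_u(x, y)
        uy, _ = cnv.mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u, p = cnv.mann_whitney_u(x, y)
            u_ref, p_ref = mann_whitney_exact_two_sided(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_for_small_n(self):
        """Tie-free n1+n2<=12: asymptotic p within 0.05 of the exact one."""
        from scipy import stats

        rng = np.random.default_rng(32)
        for _ in range(30):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x, y = rng.normal(size=n1), rng.normal(1.0, 1.0, size=n2)
            _, p_exact = cnv.mann_whitney_u(x, y)
            p_approx = float(
                stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue
            )
            assert abs(p_exact - p_approx) < 0.05


class TestGroupCNVTest:
    def make_matrix(self, focal_vals, bg_vals, feature="f1"):
        strains = [f"e{i}" for i in range(len(focal_vals))] + [
            f"c{i}" for i in range(len(bg_vals))
        ]
        groups = {s: ("focal" if s.startswith("e") else "background")
                  for s in strains}
        df = pd.DataFrame({feature: list(focal_vals) + list(bg_vals)}, index=strains)
        return CNVMatrix(values=df, groups=groups)

    def test_detects_group_shift(self):
        m = self.make_matrix([3.1, 2.9, 3.0, 3.2, 2.8], [0.1, -0.1, 0.0, 0.2, -0.2])
        (res,) = cnv.group_cnv_test(m)
        assert res.significant and res.p_value < 0.05

    def test_missing_values_excluded_pairwise(self):
        m = self.make_matrix([1.0, np.nan, 1.1], [0.0, 0.1, np.nan])
        (res,) = cnv.group_cnv_test(m)
        assert (res.n_focal, res.n_background) == (2, 2)

    def test_feature_with_empty_group_skipped(self):
        m = self.make_matrix([np.nan, np.nan], [0.0, 0.1])
        assert cnv.group_cnv_test(m) == []


class TestPearsonWithCI:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, ci = cnv.pearson_with_ci(x, x)
        assert r == 1.0 and ci == (1.0, 1.0)
        r, ci = cnv.pearson_with_ci(x, -x)
        assert r == -1.0 and ci == (-1.0, -1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        r, _ = cnv.pearson_with_ci(x, y)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (
            np.sqrt(np.mean(x**2) - x.mean() ** 2)
            * np.sqrt(np.mean(y**2) - y.mean() ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_ci_uses_fisher_z_with_standard_quantile(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        r, (lo, hi) = cnv.pearson_with_ci(x, y)
        z = np.arctanh(r)
        se = 1 / np.sqrt(30 - 3)
        assert lo == pytest.approx(np.tanh(z - 1.959964 * se))
        assert hi == pytest.approx(np.tanh(z + 1.959964 * se))
        assert lo < r < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cnv.pearson_with_ci([1, 1, 1], [1, 2, 3])


class TestReaders:
    def test_bedgraph_and_tsv_agree(self, tmp_path):
        depth = np.array([0, 0, 5, 5, 5, 2, 0, 7], dtype=np.int64)
        tsv = tmp_path / "d.tsv"
        with open(tsv, "w") as fh:
            for i, v in enumerate(depth, 1):
                fh.write(f"chr1\t{i}\t{v}\n")
        bg = tmp_path / "d.bedgraph"
        with open(bg, "w") as fh:
            fh.write("chr1\t0\t2\t0\nchr1\t2\t5\t5\nchr1\t5\t6\t2\n"
                     "chr1\t6\t7\t0\nchr1\t7\t8\t7\n")
        t1 = cnv.read_depth_tsv(tsv)
        t2 = cnv.read_bedgraph(bg)
        np.testing.assert_array_equal(t1.depths["chr1"], depth)
        np.testing.assert_array_equal(t2.depths["chr1"], depth)

    def test_features_bed_roundtrip(self, tmp_path):
        features = [
            FeatureDef("f1", "chr1", 10, 20, 2.0, 250, 250),
            FeatureDef("f2", "chr2", 5, 50, 0.5),
        ]
        path = tmp_path / "f.bed"
        synth.write_features_bed(features, path)
        back = cnv.read_features_bed(path)
        assert [(f.feature_id, f.sequence, f.start, f.end, f.reference_copies)
                for f in back] == [
            ("f1", "chr1", 10, 20, 2.0), ("f2", "chr2", 5, 50, 0.5)
        ]


class TestBackgroundOption:
    def test_median_background_robust_to_focal_amplification(self):
        depth = np.full(10_000, 50)
        depth[:4_000] = 500  # large amplification inflates the mean
        track = CoverageTrack({"c": depth})
        f = FeatureDef("f", "c", 6_000, 8_000)
        assert cnv.normalized_copy_number(track, f, background="median") == (
            pytest.approx(1.0)
        )
        assert cnv.normalized_copy_number(track, f, background="mean") < 0.3
        with pytest.raises(ValueError, match="mean.*median"):
            cnv.normalized_copy_number(track, f, background="mode")
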