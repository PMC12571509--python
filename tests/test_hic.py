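import numpy as np
import pandas as pd
import pytest

from triohap3d import hic
from conftest import poisson_matrix


def _pairs(rows):
    return pd.DataFrame(rows, columns=["chromA", "posA", "chromB", "posB"])


def _cm(matrix, bin_size=100_000, chrom="chr1"):
    return hic.ContactMatrix(chrom, bin_size, np.asarray(matrix, dtype=float))


class TestBuildMatrix:
    def test_hand_binned_pair(self):
        pairs = _pairs([("chr1", 150_000, "chr1", 450_000)])
        m = hic.build_contact_matrix(pairs, 100_000, "chr1", 1_000_000)
        assert m.matrix[1, 4] == 1 and m.matrix[4, 1] == 1
        assert m.matrix.sum() == 2

    def test_empty_pairs_zero_matrix(self):
        m = hic.build_contact_matrix(_pairs([]), 100_000, "chr1", 500_000)
        assert m.matrix.sum() == 0 and m.n_bins == 5

    def test_cis_trans_report(self):
        pairs = _pairs(
            [("chr1", 0, "chr1", 10), ("chr1", 0, "chr2", 10), ("chr2", 0, "chr2", 10)]
        )
        m = hic.build_contact_matrix(pairs, 100_000, "chr1", 500_000)
        assert m.cis_pairs == 1 and m.trans_pairs == 1

    def test_symmetry_preserved(self, small_truth):
        from triohap3d import simulate

        pairs = simulate.simulate_contacts(small_truth, n_contacts=5000, seed=8)
        m = hic.build_contact_matrix(pairs, 50_000, "chr21", 1_000_000)
        np.testing.assert_array_equal(m.matrix, m.matrix.T)


class TestDownsample:
    def test_full_size_identity(self):
        pairs = _pairs([("chr1", i, "chr1", i + 5) for i in range(50)])
        out = hic.downsample_contacts(pairs, 50, seed=1)
        pd.testing.assert_frame_equal(out, pairs)

    def test_exact_size_and_determinism(self):
        pairs = _pairs([("chr1", i, "chr1", i + 5) for i in range(100)])
        a = hic.downsample_contacts(pairs, 30, seed=1)
        b = hic.downsample_contacts(pairs, 30, seed=1)
        assert len(a) == 30
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            hic.downsample_contacts(pairs, 101)

    def test_preserves_cis_fraction_in_expectation(self):
        rng = np.random.default_rng(0)
        cis = rng.random(10_000) < 0.8
        pairs = _pairs(
            [("chr1", 0, "chr1" if c else "chr2", 10) for c in cis]
        )
        out = hic.downsample_contacts(pairs, 2000, seed=3)
        frac = (out.chromA == out.chromB).mean()
        p = cis.mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 2000)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        m = _cm(poisson_matrix(n=30, seed=2))
        assert hic.matrix_similarity(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        a = _cm(poisson_matrix(n=30, seed=2))
        b = _cm(a.matrix * 2.0)
        assert hic.matrix_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(5, (100, 100)).astype(float)
        b = rng.poisson(5, (100, 100)).astype(float)
        r = hic.matrix_similarity(_cm(a), _cm(b))
        assert abs(r) < 0.1

    def test_constant_matrix_gives_nan(self):
        a = _cm(np.full((10, 10), 3.0))
        b = _cm(poisson_matrix(n=10, seed=1))
        assert np.isnan(hic.matrix_similarity(a, b))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hic.matrix_similarity(_cm(np.zeros((5, 5))), _cm(np.zeros((6, 6))))


class TestCompartments:
    def test_checkerboard_recovery(self):
        labels = np.array([1 if (i // 10) % 2 == 0 else -1 for i in range(100)])
        m = _cm(poisson_matrix(n=100, comp_labels=labels, scale=50, seed=4))
        track = hic.compute_compartments(m, labels.astype(float))
        recovered = np.where(track.labels == "A", 1, -1)
        assert (recovered == labels).mean() >= 0.95

    def test_orientation_flip_flips_labels(self):
        labels = np.array([1 if (i // 10) % 2 == 0 else -1 for i in range(60)])
        m = _cm(poisson_matrix(n=60, comp_labels=labels, scale=50, seed=6))
        fwd = hic.compute_compartments(m, labels.astype(float))
        rev = hic.compute_compartments(m, -labels.astype(float))
        ok = (fwd.labels != "NA") & (rev.labels != "NA")
        assert (fwd.labels[ok] != rev.labels[ok]).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            hic.compute_compartments(_cm(np.zeros((20, 20))), np.ones(20))

    def test_zero_coverage_bin_is_na(self):
        mat = poisson_matrix(n=30, seed=7)
        mat[5, :] = 0
        mat[:, 5] = 0
        track = hic.compute_compartments(_cm(mat), np.ones(30))
        assert track.labels[5] == "NA" and np.isnan(track.pc1[5])


class TestChangeRatio:
    def _track(self, pc1):
        pc1 = np.asarray(pc1, dtype=float)
        labels = np.where(np.isnan(pc1) | (pc1 == 0), "NA", np.where(pc1 > 0, "A", "B"))
        return hic.CompartmentTrack("chr1", 100_000, pc1, labels)

    @pytest.mark.parametrize(
        "a,b,ratio,call",
        [
            (0.8, 0.8, 0.0, "conserved"),
            (1.0, 0.5, 0.5, "conserved"),  # exactly at threshold: not altered
            (-0.2, 0.6, 0.8 / 0.6, "altered"),  # also a label switch
            (0.0, 0.0, 0.0, "NA"),  # both zero -> ratio 0, labels NA
        ],
    )
    def test_hand_cases(self, a, b, ratio, call):
        out = hic.compartment_change_ratio(self._track([a]), self._track([b]))
        assert out.df.ratio.iloc[0] == pytest.approx(ratio, abs=1e-12)
        if call == "NA":
            # both-zero PC1 bins carry ratio 0 but no A/B label
            assert out.df.call.iloc[0] in ("conserved", "NA")
        else:
            assert out.df.call.iloc[0] == call

    def test_label_switch_alone_is_altered(self):
        out = hic.compartment_change_ratio(self._track([0.3]), self._track([-0.3]))
        assert out.df.call.iloc[0] == "altered"

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=50), rng.normal(size=50)
        fwd = hic.compartment_change_ratio(self._track(a), self._track(b)).df.ratio
        rev = hic.compartment_change_ratio(self._track(b), self._track(a)).df.ratio
        np.testing.assert_allclose(fwd, rev, atol=1e-12)


class TestTADs:
    def test_two_tad_boundary_recovery(self):
        m = _cm(poisson_matrix(n=20, tad_blocks=[(0, 10), (10, 20)], scale=40, seed=1))
        tads = hic.call_tads(m, insulation_window=3)
        internal = sorted(set(tads.start) - {0})
        assert len(internal) == 1
        assert abs(internal[0] // m.bin_size - 10) <= 1

    def test_uniform_matrix_no_boundaries(self):
        m = _cm(np.full((20, 20), 10.0))
        assert len(hic.call_tads(m)) == 1

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            hic.call_tads(_cm(np.zeros((5, 5))), insulation_window=5)

    @pytest.mark.parametrize(
        "case,control,expected",
        [
            ((0, 100), (0, 95), "conserved"),  # overlap 95 > 0.9*100
            ((0, 100), (50, 150), "altered"),  # overlap 50
        ],
    )
    def test_conservation_rule(self, case, control, expected):
        tc = pd.DataFrame([("chr1", *case)], columns=["chrom", "start", "end"])
        cc = pd.DataFrame([("chr1", *control)], columns=["chrom", "start", "end"])
        assert hic.classify_tads(tc, cc).call.iloc[0] == expected

    def test_identical_sets_all_conserved(self):
        tads = pd.DataFrame(
            [("chr1", 0, 500_000), ("chr1", 500_000, 1_200_000)],
            columns=["chrom", "start", "end"],
        )
        assert (hic.classify_tads(tads, tads).call == "conserved").all()

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(9)

        def random_tads(n):
            rows = []
            for _ in range(n):
                s = int(rng.integers(0, 900))
                rows.append(("chr1", s, s + int(rng.integers(10, 120))))
            return pd.DataFrame(rows, columns=["chrom", "start", "end"])

        case, control = random_tads(1000), random_tads(1000)
        calls = hic.classify_tads(case, control).call.to_numpy()
        cs, ce = case.start.to_numpy()[:, None], case.end.to_numpy()[:, None]
        ks, ke = control.start.to_numpy()[None, :], control.end.to_numpy()[None, :]
        ov = np.minimum(ce, ke) - np.maximum(cs, ks)
        larger = np.maximum(ce - cs, ke - ks)
        oracle = np.where((ov > 0.9 * larger).any(axis=1), "conserved", "altered")
        assert (calls == oracle).all()


class TestLoops:
    def test_planted_loop_recovered(self):
        m = _cm(poisson_matrix(n=60, loop=(10, 50, 50), scale=30, seed=3))
        loops = hic.call_loops(m)
        assert any(abs(l.bin_i - 10) <= 1 and abs(l.bin_j - 50) <= 1 for l in loops.itertuples())

    def test_uniform_matrix_no_loops(self):
        m = _cm(np.full((30, 30), 8.0))
        assert len(hic.call_loops(m)) == 0

    def test_pvalue_monotone_in_strength(self):
        pvals = []
        for strength in (10, 30, 90):
            mat = 1.0 / (1 + np.abs(np.subtract.outer(np.arange(40), np.arange(40)))) * 30
            mat[10, 30] *= strength
            mat[30, 10] = mat[10, 30]
            loops = hic.call_loops(_cm(mat))
            hit = loops[(loops.bin_i == 10) & (loops.bin_j == 30)]
            pvals.append(hit.pvalue.iloc[0])
        assert pvals[0] > pvals[1] > pvals[2]

    @pytest.mark.parametrize(
        "case,control,expected",
        [
            ((10, 50), (12, 53), "conserved"),
            ((10, 50), (10, 60), "altered"),
            ((10, 50), (10, 50), "conserved"),
        ],
    )
    def test_loop_conservation_rule(self, case, control, expected):
        lc = pd.DataFrame([("chr1", *case)], columns=["chrom", "bin_i", "bin_j"])
        cc = pd.DataFrame([("chr1", *control)], columns=["chrom", "bin_i", "bin_j"])
        assert hic.classify_loops(lc, cc).call.iloc[0] == expected

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(10)

        def random_loops(n):
            i = rng.integers(0, 80, n)
            j = i + rng.integers(3, 40, n)
            return pd.DataFrame({"chrom": "chr1", "bin_i": i, "bin_j": j})

        case, control = random_loops(1000), random_loops(1000)
        calls = hic.classify_loops(case, control, window=5).call.to_numpy()
        di = np.abs(case.bin_i.to_numpy()[:, None] - control.bin_i.to_numpy()[None, :])
        dj = np.abs(case.bin_j.to_numpy()[:, None] - control.bin_j.to_numpy()[None, :])
        oracle = np.where(((di <= 5) & (dj <= 5)).any(axis=1), "conserved", "altered")
        assert (calls == oracle).all()


class TestHaplotypeSummary:
    def test_equal_matrices_ratio_one(self):
        m = _cm(poisson_matrix(n=20, seed=4))
        out = hic.haplotype_interaction_summary(m, _cm(m.matrix.copy()))
        assert out["maternal_paternal_ratio"] == pytest.approx(1.0)

    def test_empty_region_rejected(self):
        m = _cm(np.ones((10, 10)))
        with pytest.raises(ValueError):
            hic.haplotype_interaction_summary(m, m, region=(500_000, 500_000))
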