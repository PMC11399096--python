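"""Matrix construction, LSI embedding, clustering error, Cramér's V, random
regions, peak partitioning and the naive Poisson caller."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from multitag import multimodal as mm
from multitag import simulate as sim
from tests.conftest import brute_overlaps, disjoint_regions, random_intervals


def frag_frame(rows):
    return pd.DataFrame(rows, columns=["cell", "modality", "chrom", "start", "end"])


class TestBuildMatrix:
    def test_single_fragment_single_peak(self):
        frags = frag_frame([("c1", "m", "x", 120, 180)])
        feats = pd.DataFrame({"chrom": ["x"], "start": [100], "end": [200]})
        fm = mm.build_matrix(frags, feats)
        assert fm.counts.toarray().tolist() == [[1.0]]

    def test_fragment_spanning_bin_boundary_counts_in_both(self):
        frags = frag_frame([("c1", "m", "x", 4990, 5010)])
        bins = mm.make_bins({"x": 10_000}, width=5000)
        fm = mm.build_matrix(frags, bins)
        assert fm.counts.toarray().tolist() == [[1.0, 1.0]]

    def test_unknown_chromosome_counted_and_skipped(self):
        frags = frag_frame([("c1", "m", "x", 0, 10), ("c1", "m", "y", 0, 10)])
        feats = pd.DataFrame({"chrom": ["x"], "start": [0], "end": [100]})
        fm = mm.build_matrix(frags, feats)
        assert fm.n_unknown_chrom == 1
        assert fm.counts.sum() == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_overlap_matrix(self, seed):
        rng = np.random.default_rng(100 + seed)
        frags = random_intervals(rng, 120)
        frags["cell"] = rng.choice(["a", "b", "c"], size=len(frags))
        frags["modality"] = "m"
        feats = disjoint_regions(rng, 30)
        fm = mm.build_matrix(frags, feats)
        cells = fm.cells
        expected = np.zeros((len(cells), len(fm.regions)))
        for _, f in frags.iterrows():
            for j, p in fm.regions.iterrows():
                if brute_overlaps(f, p):
                    expected[cells.index(f["cell"]), j] += 1
        np.testing.assert_array_equal(fm.counts.toarray(), expected)
        assert fm.counts.sum() == expected.sum()  # conservation


def block_matrix(n_per_type=40, n_regions=60, depth=20, seed=0):
    """Block-diagonal two-type count matrix: type 0 hits the first half of the
    regions, type 1 the second half."""
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    X = np.zeros((2 * n_per_type, n_regions))
    for i in range(2 * n_per_type):
        block = slice(0, half) if i < n_per_type else slice(half, n_regions)
        cols = rng.choice(np.arange(n_regions)[block], size=depth)
        np.add.at(X[i], cols, 1)
    cells = [f"c{i}" for i in range(2 * n_per_type)]
    regions = pd.DataFrame(
        {"chrom": "x", "start": np.arange(n_regions) * 1000,
         "end": np.arange(n_regions) * 1000 + 500}
    )
    return mm.FeatureMatrix(cells, regions, scipy.sparse.csr_matrix(X))


class TestLsi:
    def test_block_diagonal_types_separate_cleanly(self):
        fm = block_matrix()
        emb = mm.tfidf_lsi(fm, d=5)
        comp = emb.coords[:, 0]
        a, b = comp[:40], comp[40:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or max(
            b.min(), a.min()
        ) > min(b.max(), a.max())  # projections do not overlap
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicating_cells_preserves_pairwise_distances(self):
        fm = block_matrix(seed=3)
        emb1 = mm.tfidf_lsi(fm, d=5, drop_depth_component=False)
        X2 = scipy.sparse.vstack([fm.counts, fm.counts]).tocsr()
        fm2 = mm.FeatureMatrix(
            [f"{c}_{r}" for r in ("a", "b") for c in fm.cells], fm.regions, X2
        )
        emb2 = mm.tfidf_lsi(fm2, d=5, drop_depth_component=False)
        n = len(fm.cells)
        d1 = np.linalg.norm(emb1.coords[:, None] - emb1.coords[None], axis=-1)
        first = emb2.coords[:n]
        d2 = np.linalg.norm(first[:, None] - first[None], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_single_active_region_is_rank_one(self):
        X = np.zeros((30, 25))
        X[:, 3] = np.arange(1, 31)
        fm = mm.FeatureMatrix(
            [f"c{i}" for i in range(30)],
            pd.DataFrame({"chrom": "x", "start": np.arange(25) * 100,
                          "end": np.arange(25) * 100 + 50}),
            scipy.sparse.csr_matrix(X),
        )
        emb = mm.tfidf_lsi(fm, d=3, drop_depth_component=False)
        assert emb.singular_values[0] > 0
        assert (emb.singular_values[1:] < 1e-8 * emb.singular_values[0]).all()

    def test_all_zero_matrix_rejected(self):
        fm = mm.FeatureMatrix(
            ["a", "b"],
            pd.DataFrame({"chrom": ["x"], "start": [0], "end": [10]}),
            scipy.sparse.csr_matrix((2, 1)),
        )
        with pytest.raises(ValueError):
            mm.tfidf_lsi(fm, d=1)

    def test_depth_correlation_reported(self):
        fm = block_matrix(seed=5)
        emb = mm.tfidf_lsi(fm, d=5, drop_depth_component=False)
        assert emb.depth_correlation.shape == (5,)
        assert np.all(np.abs(emb.depth_correlation) <= 1.0)


class TestClustering:
    def test_separated_blobs_recovered_perfectly(self):
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0, 0.1, (50, 3)), rng.normal(5, 0.1, (50, 3))]
        )
        truth = np.repeat([0, 1], 50)
        for method in ("hierarchical", "kmeans"):
            labels = mm.cluster_cells(pts, 2, method=method, seed=1)
            assert mm.cluster_error_rate(labels, truth) == 0.0

    def test_k_one_and_k_too_large(self):
        pts = np.zeros((5, 2))
        assert (mm.cluster_cells(pts, 1) == 0).all()
        with pytest.raises(ValueError):
            mm.cluster_cells(pts, 6)

    def test_error_rate_permutation_invariance(self):
        truth = np.repeat([0, 1], 10)
        assert mm.cluster_error_rate(truth, truth) == 0.0
        assert mm.cluster_error_rate(1 - truth, truth) == 0.0

    def test_random_labels_err_near_half(self):
        rng = np.random.default_rng(1)
        n = 10_000
        truth = np.repeat([0, 1], n // 2)
        labels = rng.integers(0, 2, size=n)
        err = mm.cluster_error_rate(labels, truth)
        se = 0.5 / np.sqrt(n)
        # permutation minimum pulls the estimate just below 1/2
        assert 0.5 - 4 * se <= err <= 0.5


class TestNormalizedSignal:
    def test_identical_cells_give_zero_z(self):
        frags = frag_frame([(f"c{i}", "m", "x", 10, 20) for i in range(5)])
        peaks = pd.DataFrame({"chrom": ["x"], "start": [0], "end": [100]})
        z = mm.normalized_signal({"m": frags}, peaks)
        np.testing.assert_allclose(z["m"].to_numpy(), 0.0)

    def test_z_normalisation_identity(self, two_type_sim):
        frags = two_type_sim["fragments"]
        z = mm.normalized_signal({"drug": frags}, two_type_sim["peaks_a"])
        vals = z["drug"].dropna().to_numpy()
        assert abs(vals.mean()) < 1e-9
        assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_sign_of_mean_z_separates_types(self, two_type_sim):
        frags = two_type_sim["fragments"]
        truth = two_type_sim["truth_types"]
        z = mm.normalized_signal({"drug": frags}, two_type_sim["peaks_a"])
        by_type = z["drug"].groupby(truth.reindex(z.index)).mean()
        assert by_type["typeA"] > 0 > by_type["typeB"]


class TestCramersV:
    def test_hand_table(self):
        """Regions engineered to the 2x2 table [[40,10],[10,40]] give
        V = 1500/2500 = 0.6 exactly."""
        regions = pd.DataFrame(
            {"chrom": "x", "start": np.arange(100) * 1000,
             "end": np.arange(100) * 1000 + 100}
        )
        rows_a, rows_b = [], []
        for i in range(100):
            s = i * 1000
            if i < 40:  # both
                rows_a.append(("c", "A", "x", s, s + 50))
                rows_b.append(("c", "B", "x", s, s + 50))
            elif i < 50:  # A only
                rows_a.append(("c", "A", "x", s, s + 50))
            elif i < 60:  # B only
                rows_b.append(("c", "B", "x", s, s + 50))
        v, summary = mm.cramers_v(frag_frame(rows_a), frag_frame(rows_b), regions)
        assert v["c"] == pytest.approx(0.6)
        assert summary["median"] == pytest.approx(0.6)

    def test_identical_occupancy_gives_one(self):
        regions = pd.DataFrame(
            {"chrom": "x", "start": np.arange(10) * 1000,
             "end": np.arange(10) * 1000 + 100}
        )
        rows = [("c", "A", "x", i * 1000, i * 1000 + 50) for i in range(5)]
        rows_b = [(c, "B", ch, s, e) for c, _, ch, s, e in rows]
        v, _ = mm.cramers_v(frag_frame(rows), frag_frame(rows_b), regions)
        assert v["c"] == pytest.approx(1.0)

    def test_degenerate_margin_excluded(self):
        regions = pd.DataFrame(
            {"chrom": "x", "start": [0, 1000], "end": [100, 1100]}
        )
        # modality A hits every region -> degenerate margin
        fa = frag_frame([("c", "A", "x", 0, 50), ("c", "A", "x", 1000, 1050)])
        fb = frag_frame([("c", "B", "x", 0, 50)])
        v, summary = mm.cramers_v(fa, fb, regions)
        assert np.isnan(v["c"])
        assert summary["n_excluded"] == 1

    def test_too_few_regions_rejected(self):
        regions = pd.DataFrame({"chrom": ["x"], "start": [0], "end": [100]})
        f = frag_frame([("c", "A", "x", 0, 50)])
        with pytest.raises(ValueError):
            mm.cramers_v(f, f, regions)

    def test_independent_modalities_have_null_median(self):
        rng = np.random.default_rng(7)
        n_regions, n_cells, hits = 2000, 30, 300
        regions = pd.DataFrame(
            {"chrom": "x", "start": np.arange(n_regions) * 1000,
             "end": np.arange(n_regions) * 1000 + 200}
        )
        rows_a, rows_b = [], []
        for c in range(n_cells):
            for mod, rows in (("A", rows_a), ("B", rows_b)):
                for r in rng.choice(n_regions, size=hits, replace=False):
                    rows.append((f"c{c}", mod, "x", r * 1000, r * 1000 + 100))
        _, summary = mm.cramers_v(frag_frame(rows_a), frag_frame(rows_b), regions)
        assert summary["median"] < 0.05


class TestRandomRegions:
    def test_count_and_width_multiset_preserved(self):
        rng = np.random.default_rng(2)
        template = disjoint_regions(rng, 40, width=150, gap=300)
        out = mm.random_regions({"hs_chr1": 200_000, "mm_chr1": 200_000}, template, seed=3)
        assert len(out) == len(template)
        assert sorted(out["end"] - out["start"]) == sorted(
            template["end"] - template["start"]
        )
        for chrom, g in out.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_infeasible_template_fails(self):
        template = pd.DataFrame({"chrom": ["x"], "start": [0], "end": [500]})
        with pytest.raises(ValueError):
            mm.random_regions({"c": 100}, template, seed=0)


class TestPeakPartition:
    def test_disjoint_and_identical_sets(self):
        a = pd.DataFrame({"chrom": "x", "start": [0, 1000], "end": [100, 1100]})
        b = pd.DataFrame({"chrom": "x", "start": [5000], "end": [5100]})
        part = mm.specific_shared_peaks(a, b)
        assert len(part.a_specific) == 2 and len(part.a_shared) == 0
        assert len(part.b_specific) == 1
        part2 = mm.specific_shared_peaks(a, a.copy())
        assert len(part2.a_shared) == 2 and len(part2.a_specific) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_partition(self, seed):
        rng = np.random.default_rng(seed)
        a = disjoint_regions(rng, 25, width=180, gap=250)
        b = disjoint_regions(rng, 25, width=180, gap=250)
        part = mm.specific_shared_peaks(a, b)
        assert len(part.a_specific) + len(part.a_shared) == len(a)
        assert len(part.b_specific) + len(part.b_shared) == len(b)
        expected_shared_a = sum(
            any(brute_overlaps(pa, pb) for _, pb in b.iterrows())
            for _, pa in a.iterrows()
        )
        assert len(part.a_shared) == expected_shared_a


class TestNaivePeakCall:
    def test_uniform_background_calibrated(self):
        rng = np.random.default_rng(9)
        n = 60_000
        starts = rng.integers(0, 10_000_000 - 200, size=n)
        frags = frag_frame(
            [("c", "m", "x", 0, 1)] * 0
        )
        frags = pd.DataFrame(
            {"cell": "c", "modality": "m", "chrom": "x", "start": starts,
             "end": starts + 200}
        )
        peaks = mm.naive_peak_call(frags, {"x": 10_000_000}, bin_width=500, q=0.01)
        n_bins = 10_000_000 // 500
        sig_bins = (peaks["end"] - peaks["start"]).sum() / 500
        # BH controls the false-discovery fraction under the null
        assert sig_bins / n_bins <= 0.01

    def test_strong_spike_called(self):
        rng = np.random.default_rng(10)
        starts = rng.integers(0, 100_000, size=2000)
        bg = pd.DataFrame({"cell": "c", "modality": "m", "chrom": "x",
                           "start": starts, "end": starts + 100})
        spike_starts = rng.integers(50_000, 50_400, size=500)
        spike = pd.DataFrame({"cell": "c", "modality": "m", "chrom": "x",
                              "start": spike_starts, "end": spike_starts + 100})
        peaks = mm.naive_peak_call(pd.concat([bg, spike]), {"x": 100_000})
        assert any((p.start <= 50_200 < p.end) for p in peaks.itertuples())

    def test_recovers_simulated_peaks(self, tiny_genome):
        rng = np.random.default_rng(11)
        truth_peaks = sim.sample_peaks(tiny_genome.sizes_for("hs"), 20,
                                       width_median=800, min_gap=3000, rng=rng)
        cells = pd.DataFrame({"cell_id": range(50), "species": "hs",
                              "cell_type": "a",
                              "cell_key": [f"c{i}" for i in range(50)]})
        prof = {("m", "a"): sim.SignalProfile(truth_peaks, 0.8, 400,
                                              frag_len_median=150)}
        frags = sim.simulate_fragments(cells, prof, tiny_genome, rng)
        called = mm.naive_peak_call(frags, tiny_genome.sizes_for("hs"))
        from multitag._intervals import overlaps_any

        recovered = overlaps_any(truth_peaks, called).mean()
        assert recovered >= 0.9
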