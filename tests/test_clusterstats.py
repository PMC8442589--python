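import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oscillotap.clusterstats import (
    Cluster,
    ClusterPermutationTest,
    PairedTFRSample,
    T_SENTINEL,
    extract_clusters,
    paired_t_map,
    permutation_null,
    window_stats,
    zscore_normalize,
)
from oscillotap.reference_data import FAST_140BPM, SLOW_70BPM, reference_column


def brute_force_t(values):
    """Closed-form one-sample t, written independently of the implementation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    m = values.sum() / n
    s = np.sqrt(((values - m) ** 2).sum() / (n - 1))
    return m / (s / np.sqrt(n))


def brute_force_clusters(mask, tmap):
    """4-connected components by BFS; returns sorted cluster masses."""
    seen = np.zeros_like(mask, dtype=bool)
    masses = []
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] and not seen[i, j]:
                stack, total = [(i, j)], 0.0
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    total += tmap[r, c]
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                masses.append(total)
    return sorted(masses)


class TestPairedTMap:
    def test_matches_closed_form_everywhere(self, rng):
        diffs = rng.standard_normal((12, 6, 9))
        tmap = paired_t_map(diffs)
        for i, j in [(0, 0), (3, 5), (5, 8)]:
            assert tmap[i, j] == pytest.approx(brute_force_t(diffs[:, i, j]), abs=1e-10)

    def test_all_zero_differences_give_zero_t(self):
        assert np.all(paired_t_map(np.zeros((5, 3, 3))) == 0.0)

    def test_reference_column_in_one_cell(self):
        diffs = np.zeros((20, 2, 2))
        diffs[:, 1, 1] = reference_column(70.0, "Relaxing-ToneOnly", "FCz")
        tmap = paired_t_map(diffs)
        assert tmap[1, 1] == pytest.approx(2.67, abs=0.005)

    def test_zero_variance_nonzero_mean_hits_sentinel(self):
        diffs = np.ones((4, 2, 2))
        diffs[:, 0, 0] = [1.0, -1.0, 1.0, -1.0]
        tmap = paired_t_map(diffs)
        assert tmap[1, 1] == T_SENTINEL
        assert abs(tmap[0, 0]) < 1.0

    def test_label_swap_negates_map(self, rng):
        diffs = rng.standard_normal((8, 4, 4))
        assert np.allclose(paired_t_map(-diffs), -paired_t_map(diffs))


class TestClusterExtraction:
    def test_two_rectangular_blobs(self):
        tmap = np.zeros((6, 8))
        tmap[1:3, 1:3] = 5.0
        tmap[4:6, 5:8] = -4.0
        clusters = extract_clusters(tmap, df=19)
        assert len(clusters) == 2
        by_sign = {c.sign: c for c in clusters}
        assert by_sign[1].mass == pytest.approx(20.0)
        assert by_sign[-1].mass == pytest.approx(-24.0)

    def test_diagonal_touch_stays_two_clusters(self):
        tmap = np.zeros((4, 4))
        tmap[0, 0] = tmap[1, 1] = 6.0
        clusters = extract_clusters(tmap, df=19)
        assert len(clusters) == 2

    def test_subthreshold_map_gives_no_clusters(self):
        assert extract_clusters(np.full((5, 5), 1.0), df=19) == []

    def test_masses_match_brute_force(self, rng):
        tmap = rng.standard_normal((10, 15)) * 3
        t_crit = stats.t.ppf(0.975, 19)
        clusters = extract_clusters(tmap, df=19)
        expected = (brute_force_clusters(tmap > t_crit, tmap)
                    + brute_force_clusters(tmap < -t_crit, tmap))
        assert sorted(c.mass for c in clusters) == pytest.approx(sorted(expected))


class TestPermutationNull:
    def test_seed_reproducibility(self, rng):
        diffs = rng.standard_normal((10, 5, 5))
        a = permutation_null(diffs, n_permutations=200, seed=42)
        b = permutation_null(diffs, n_permutations=200, seed=42)
        assert np.array_equal(a.pos_extremes, b.pos_extremes)
        assert a.threshold_pos == b.threshold_pos

    def test_minimum_sizes_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_null(rng.standard_normal((1, 3, 3)), n_permutations=200)
        with pytest.raises(ValueError):
            permutation_null(rng.standard_normal((8, 3, 3)), n_permutations=50)

    def test_tiny_grid_null_matches_full_enumeration(self, rng):
        """Monte-Carlo sign-flip null vs exhaustive enumeration (n=4, 3x3)."""
        diffs = rng.standard_normal((4, 3, 3)) * 2.0
        t_crit = stats.t.ppf(0.975, 3)
        pos_exact, neg_exact = [], []
        for signs in itertools.product((1.0, -1.0), repeat=4):
            flipped = diffs * np.array(signs)[:, None, None]
            tmap = np.array([[brute_force_t(flipped[:, i, j]) for j in range(3)]
                             for i in range(3)])
            pm = brute_force_clusters(tmap > t_crit, tmap)
            nm = brute_force_clusters(tmap < -t_crit, tmap)
            pos_exact.append(max(pm) if pm else 0.0)
            neg_exact.append(min(nm) if nm else 0.0)
        null = permutation_null(diffs, n_permutations=1000, seed=5)
        # every Monte-Carlo extreme must be an enumerated value
        assert np.all(np.isclose(null.pos_extremes[:, None], np.array(pos_exact)[None, :],
                                 atol=1e-8).any(axis=1))
        # thresholds agree within Monte-Carlo (order-statistic) error
        assert (np.percentile(pos_exact, 85) - 1e-9 <= null.threshold_pos
                <= max(pos_exact) + 1e-9)
        assert (min(neg_exact) - 1e-9 <= null.threshold_neg
                <= np.percentile(neg_exact, 15) + 1e-9)


class TestWindowStats:
    def test_slow_relaxing_tone_fcz_reproduces_reported_statistics(self):
        ws = window_stats(reference_column(70.0, "Relaxing-ToneOnly", "FCz"), None)
        assert ws.mean_difference == pytest.approx(1.30, abs=0.005)
        assert ws.ci95[0] == pytest.approx(0.28, abs=0.005)
        assert ws.ci95[1] == pytest.approx(2.32, abs=0.005)
        assert ws.t == pytest.approx(2.67, abs=0.005)
        assert ws.df == 19
        assert ws.p_value < 0.02
        assert ws.cohens_d == pytest.approx(ws.t / np.sqrt(20), abs=1e-12)

    def test_slow_activating_relaxing_c4(self):
        ws = window_stats(reference_column(70.0, "Activating-Relaxing", "C4"), None)
        assert ws.mean_difference == pytest.approx(-1.23, abs=0.005)
        assert abs(ws.t) == pytest.approx(2.8185, abs=0.005)

    def test_all_zero_differences(self):
        ws = window_stats(np.zeros(20), None)
        assert ws.mean_difference == 0.0
        assert ws.t == 0.0
        assert ws.cohens_d == 0.0
        assert ws.ci95 == (0.0, 0.0)

    def test_window_averaging_over_cluster_bounds(self, rng):
        diffs = rng.standard_normal((10, 6, 6))
        cluster = Cluster(cells=((1, 2), (1, 3), (2, 2)), mass=9.0, sign=1)
        ws = window_stats(diffs, cluster)
        manual = diffs[:, 1:3, 2:4].mean(axis=(1, 2))
        assert ws.mean_difference == pytest.approx(manual.mean())
        assert ws.t == pytest.approx(brute_force_t(manual), abs=1e-10)


class TestZScore:
    def test_pooled_mean_zero_sd_one_per_participant(self, rng):
        maps = {c: rng.standard_normal((6, 4, 5)) * 3 + 1 for c in "abcdef"}
        z = zscore_normalize(maps)
        for p in range(6):
            pooled = np.concatenate([z[c][p].ravel() for c in maps])
            assert abs(pooled.mean()) < 1e-10
            assert abs(pooled.std() - 1.0) < 1e-10

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(4)
        maps = {c: rng.standard_normal((3, 2, 2)) for c in ("x", "y")}
        z1 = zscore_normalize(maps)
        z2 = zscore_normalize({c: a * v + b for c, v in maps.items()})
        for c in maps:
            assert np.allclose(z1[c], z2[c], atol=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize({"x": np.ones((2, 2, 2)), "y": np.ones((2, 2, 2))})


class TestModelInterface:
    def test_fit_and_summary(self, rng):
        a = rng.standard_normal((10, 8, 12))
        b = rng.standard_normal((10, 8, 12))
        a[:, 2:5, 3:7] += 2.0
        model = ClusterPermutationTest(a, b)
        res = model.fit(n_permutations=200, seed=1)
        assert res.tmap.shape == (8, 12)
        text = res.summary()
        assert "permutations: 200" in text
        report = res.to_report()
        assert set(report) >= {"clusters", "threshold_pos", "threshold_neg"}

    def test_significant_cluster_recovers_injected_region(self, rng):
        a = rng.standard_normal((12, 10, 10))
        b = rng.standard_normal((12, 10, 10))
        a[:, 2:5, 2:6] += 3.0
        res = ClusterPermutationTest(a, b).fit(n_permutations=300, seed=2)
        sig = res.significant_clusters
        assert sig
        f0, f1, t0, t1 = max(sig, key=lambda c: c.mass).bounds
        assert f0 <= 4 and f1 >= 2 and t0 <= 5 and t1 >= 2

    def test_from_dataframe_matches_array_path(self, rng):
        a = rng.standard_normal((3, 2, 2))
        b = rng.standard_normal((3, 2, 2))
        rows = []
        for cond, cube in (("A", a), ("B", b)):
            for p in range(3):
                for fi, f in enumerate((10.0, 20.0)):
                    for ti, t in enumerate((0.0, 4.0)):
                        rows.append({"participant": p, "condition": cond,
                                     "frequency": f, "time": t,
                                     "db": cube[p, fi, ti]})
        model_df = ClusterPermutationTest.from_dataframe(pd.DataFrame(rows),
                                                         conditions=("A", "B"))
        model_arr = ClusterPermutationTest(a, b)
        assert np.allclose(model_df.diffs, model_arr.diffs)

    def test_sample_shape_validation(self, rng):
        with pytest.raises(ValueError):
            PairedTFRSample(rng.standard_normal((5, 2, 2)), rng.standard_normal((4, 2, 2)))
        with pytest.raises(ValueError):
            ClusterPermutationTest(rng.standard_normal((1, 2, 2)))
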