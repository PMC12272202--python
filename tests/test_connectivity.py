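"""Seed-target correlation metrics: degree, strength, variance, ratios."""

import numpy as np
import pytest

from vasconn.connectivity import (
    PerSeedRow,
    category_metrics,
    connectivity_maps,
    degree_map,
    group_summarize,
    ratio_maps,
    seed_target_correlations,
    strength_variance_maps,
)
from vasconn.phantom import PhantomSpec, make_phantom

from conftest import make_bold, mask_from_array


def dense_reference_maps(bold, seeds, targets, threshold, mode):
    """Independent brute-force recomputation: full correlation matrix via
    np.corrcoef, then per-seed metrics by direct enumeration."""
    n_t = bold.n_volumes
    Y = bold.data.reshape(-1, n_t)
    s_idx = seeds.flat_indices()
    t_idx = targets.flat_indices()
    t_valid = t_idx[Y[t_idx].std(axis=1) > 0]
    out = {k: [] for k in ("D", "S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all")}
    for sf in s_idx:
        if Y[sf].std() == 0:
            for k in out:
                out[k].append(np.nan)
            continue
        r = np.array(
            [np.corrcoef(Y[sf], Y[tf])[0, 1] for tf in t_valid if tf != sf]
        )
        pos, neg = r[r > 0], r[r < 0]
        out["D"].append(
            float((np.abs(r) > threshold).sum() if mode == "absolute" else (r > threshold).sum())
        )
        out["S_pos"].append(pos.mean() if pos.size else np.nan)
        out["S_neg"].append(neg.mean() if neg.size else np.nan)
        out["S_all"].append(r.mean() if r.size else np.nan)
        out["var_pos"].append(pos.var() if pos.size else np.nan)
        out["var_neg"].append(neg.var() if neg.size else np.nan)
        out["var_all"].append(r.var() if r.size else np.nan)
    return {k: np.asarray(v) for k, v in out.items()}


class TestCorrelationStream:
    def bold_pair(self, x, y):
        data = np.stack([x, y]).reshape(2, 1, 1, -1).astype(float)
        return make_bold(data)

    def test_identical_series_correlate_to_one(self):
        bold = self.bold_pair([1, 2, 3], [1, 2, 3])
        all_mask = mask_from_array(np.ones((2, 1, 1), bool))
        rows = list(seed_target_correlations(bold, all_mask, all_mask))
        assert rows[0].r[0] == pytest.approx(1.0, abs=1e-12)

    def test_reversed_series_correlate_to_minus_one(self):
        bold = self.bold_pair([1, 2, 3], [3, 2, 1])
        all_mask = mask_from_array(np.ones((2, 1, 1), bool))
        rows = list(seed_target_correlations(bold, all_mask, all_mask))
        assert rows[0].r[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("block_size", [1, 7, 64, 1000])
    def test_blocked_equals_dense_oracle(self, rng, block_size):
        bold = make_bold(rng.standard_normal((5, 4, 3, 30)))
        seeds = mask_from_array(rng.random((5, 4, 3)) < 0.4)
        targets = mask_from_array(rng.random((5, 4, 3)) < 0.6)
        Y = bold.data.reshape(-1, 30)
        t_idx = targets.flat_indices()
        oracle = np.corrcoef(Y)  # full matrix in one shot
        for row in seed_target_correlations(bold, seeds, targets, block_size):
            expected = np.array([oracle[row.seed_flat, tf] for tf in t_idx if tf != row.seed_flat])
            assert np.abs(row.r - expected).max() <= 1e-10

    def test_symmetry(self, rng):
        bold = make_bold(rng.standard_normal((3, 3, 1, 25)))
        m = mask_from_array(np.ones((3, 3, 1), bool))
        rows = {row.seed_flat: row for row in seed_target_correlations(bold, m, m)}
        idx = m.flat_indices()
        r_ab = rows[idx[0]].r[0]  # seed 0 vs target 1 (self removed)
        r_ba = rows[idx[1]].r[0]  # seed 1 vs target 0
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_zero_variance_target_dropped(self, rng):
        data = rng.standard_normal((3, 1, 1, 20))
        data[1, 0, 0] = 5.0  # constant
        bold = make_bold(data)
        m = mask_from_array(np.ones((3, 1, 1), bool))
        rows = list(seed_target_correlations(bold, m, m))
        assert rows[0].n_targets_valid == 1  # one valid non-self target left
        assert rows[1].r is None  # constant seed undefined

    def test_all_zero_variance_seeds_rejected(self):
        bold = make_bold(np.ones((2, 1, 1, 20)))
        m = mask_from_array(np.ones((2, 1, 1), bool))
        with pytest.raises(ValueError, match="zero variance"):
            list(seed_target_correlations(bold, m, m))


class TestRowMetrics:
    def test_degree_enumeration_absolute_and_positive(self):
        rows = [PerSeedRow(0, np.array([0.9, 0.1, -0.3]), 3)]
        assert degree_map(rows, threshold=0.15, mode="absolute")[0] == 2
        rows = [PerSeedRow(0, np.array([0.9, 0.1, -0.3]), 3)]
        assert degree_map(rows, threshold=0.15, mode="positive")[0] == 1

    def test_strength_variance_hand_computed(self):
        sv = strength_variance_maps([PerSeedRow(0, np.array([0.4, -0.2, 0.6]), 3)])
        assert sv["S_pos"][0] == pytest.approx(0.5)
        assert sv["S_neg"][0] == pytest.approx(-0.2)
        assert sv["var_pos"][0] == pytest.approx(0.01)  # population variance
        assert sv["var_neg"][0] == pytest.approx(0.0)

    def test_empty_sign_class_undefined(self):
        sv = strength_variance_maps([PerSeedRow(0, np.array([-0.4, -0.1]), 2)])
        assert np.isnan(sv["S_pos"][0])
        assert sv["n_pos"][0] == 0

    def test_constant_positive_class_zero_variance(self):
        sv = strength_variance_maps([PerSeedRow(0, np.array([0.3, 0.3, 0.3]), 3)])
        assert sv["var_pos"][0] == 0.0

    def test_degree_threshold_validation(self):
        with pytest.raises(ValueError):
            degree_map([], threshold=1.5)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(7)
    shape = (5, 4, 3)
    bold = make_bold(rng.standard_normal((*shape, 40)))
    labels = np.zeros(shape, np.int16)
    labels.ravel()[[0, 7, 14, 21]] = 1
    labels.ravel()[[3, 11, 19, 27, 35]] = 2
    artery = mask_from_array(labels == 1)
    vein = mask_from_array(labels == 2)
    gm = mask_from_array(rng.random(shape) < 0.7)
    return bold, artery, vein, gm


class TestCategories:
    def test_all_categories_match_dense_oracle(self, toy):
        bold, artery, vein, gm = toy
        cats = category_metrics(bold, artery, vein, gm, threshold=0.15, mode="absolute")
        pairs = {
            "VV": (vein, vein), "AA": (artery, artery), "AV": (artery, vein),
            "VA": (vein, artery), "V_GM": (vein, gm), "A_GM": (artery, gm),
            "GM_GM": (gm, gm),
        }
        for name, (s, t) in pairs.items():
            ref = dense_reference_maps(bold, s, t, 0.15, "absolute")
            for metric, vals in ref.items():
                got = cats[name].metric(metric)
                assert np.allclose(got, vals, atol=1e-10, equal_nan=True), (name, metric)

    def test_noiseless_phantom_vv_degree_saturates(self):
        ph = make_phantom(PhantomSpec(noise_sd=0.0, gm_noise_sd=0.0))
        vein = ph.labels.vein_mask()
        maps = connectivity_maps(ph.bold, vein, vein, threshold=0.5)
        assert (maps.D == vein.n_true - 1).all()

    def test_transpose_pair_count_conserved(self, toy):
        bold, artery, vein, gm = toy
        cats = category_metrics(bold, artery, vein, gm, categories=("AV", "VA"))
        assert np.nansum(cats["AV"].D) == np.nansum(cats["VA"].D)

    def test_degree_antitone_in_threshold(self, toy):
        bold, artery, vein, gm = toy
        prev = None
        for thr in (0.1, 0.2, 0.4, 0.8):
            d = connectivity_maps(bold, vein, gm, threshold=thr).D
            if prev is not None:
                assert (d <= prev).all()
            prev = d

    def test_overlapping_masks_rejected(self, toy):
        bold, artery, vein, gm = toy
        with pytest.raises(ValueError, match="overlap"):
            category_metrics(bold, artery, artery, gm)

    def test_degree_bounded_by_valid_targets(self, toy):
        bold, artery, vein, gm = toy
        m = connectivity_maps(bold, vein, gm)
        ok = ~np.isnan(m.D)
        assert (m.D[ok] >= 0).all() and (m.D[ok] <= m.n_targets_valid[ok]).all()


class TestRatios:
    def test_simple_arithmetic(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 2, 30)))
        seeds = mask_from_array(rng.random((4, 4, 2)) < 0.3)
        small = mask_from_array(rng.random((4, 4, 2)) < 0.3)
        big = mask_from_array(small.data | (rng.random((4, 4, 2)) < 0.5))
        num = connectivity_maps(bold, seeds, small, threshold=0.2)
        den = connectivity_maps(bold, seeds, big, threshold=0.2)
        rm = ratio_maps(num, den)
        expected = np.where(den.D > 0, num.D / den.D, np.nan)
        assert np.allclose(rm.D_ratio, expected, equal_nan=True)

    def test_subset_targets_bound_ratio_by_one(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 2, 30)))
        seeds = mask_from_array(rng.random((4, 4, 2)) < 0.4)
        sub = mask_from_array(rng.random((4, 4, 2)) < 0.3)
        sup = mask_from_array(sub.data | (rng.random((4, 4, 2)) < 0.4))
        rm = ratio_maps(
            connectivity_maps(bold, seeds, sub), connectivity_maps(bold, seeds, sup)
        )
        defined = ~np.isnan(rm.D_ratio)
        assert (rm.D_ratio[defined] <= 1.0 + 1e-12).all()

    def test_seed_mismatch_rejected(self, rng):
        bold = make_bold(rng.standard_normal((4, 4, 2, 30)))
        s1 = mask_from_array(rng.random((4, 4, 2)) < 0.4)
        s2 = mask_from_array(rng.random((4, 4, 2)) < 0.4)
        t = mask_from_array(np.ones((4, 4, 2), bool))
        with pytest.raises(ValueError, match="seed"):
            ratio_maps(connectivity_maps(bold, s1, t), connectivity_maps(bold, s2, t))


class TestGroupSummary:
    def fake_maps(self, d_values):
        from vasconn.connectivity import ConnectivityMaps
        from vasconn.grid import VolumeGrid

        n = len(d_values)
        grid = VolumeGrid.from_spacing((n, 1, 1), (4.0,) * 3)
        nanarr = np.full(n, np.nan)
        return ConnectivityMaps(
            category="VV", grid=grid, seed_flat=np.arange(n), threshold=0.15,
            mode="absolute", D=np.asarray(d_values, float), S_pos=nanarr, S_neg=nanarr,
            S_all=nanarr, var_pos=nanarr, var_neg=nanarr, var_all=nanarr,
            n_pos=np.zeros(n), n_neg=np.zeros(n), n_targets_valid=np.full(n, 10),
        )

    def test_group_mean_of_two_sessions(self):
        gs = group_summarize([{"VV": self.fake_maps([2, 2])}, {"VV": self.fake_maps([4, 4])}])
        row = gs.group[(gs.group.category == "VV") & (gs.group.metric == "D")]
        assert row["mean"].iloc[0] == pytest.approx(3.0)

    def test_single_session_identity(self):
        gs = group_summarize([{"VV": self.fake_maps([1, 2, 3])}])
        row = gs.group[(gs.group.category == "VV") & (gs.group.metric == "D")]
        assert row["mean"].iloc[0] == pytest.approx(2.0)
        assert row["n_sessions"].iloc[0] == 1

    def test_five_sessions_match_tabular_oracle(self, rng):
        session_means = []
        sessions = []
        for _ in range(5):
            d = rng.integers(0, 9, size=6).astype(float)
            sessions.append({"VV": self.fake_maps(d)})
            session_means.append(d.mean())
        gs = group_summarize(sessions)
        row = gs.group[(gs.group.category == "VV") & (gs.group.metric == "D")]
        assert row["mean"].iloc[0] == pytest.approx(np.mean(session_means))
        assert row["median"].iloc[0] == pytest.approx(np.median(session_means))
        assert row["q1"].iloc[0] == pytest.approx(np.percentile(session_means, 25))

    def test_all_undefined_metric_stays_undefined(self):
        gs = group_summarize([{"VV": self.fake_maps([1.0])}])
        row = gs.group[(gs.group.category == "VV") & (gs.group.metric == "S_pos")]
        assert np.isnan(row["mean"].iloc[0])
        assert row["n_sessions"].iloc[0] == 0

    def test_no_sessions_rejected(self):
        with pytest.raises(ValueError):
            group_summarize([])
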