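"""Maxent-lite fitting, overlap statistics, and the randomization tests."""

import numpy as np
import pytest

from hzkit.io_formats import EnvStack, OccurrenceSet
from hzkit.niche import (
    NicheModelConfig,
    auc_presence_background,
    background_similarity_test,
    fit_maxent_lite,
    identity_test,
    model_overlap,
    overlap_stats,
    prune_correlated_variables,
    sample_background_points,
    select_model_grid,
)
from hzkit.synthetic_data import NicheScenario, make_occurrence_scenario

CFG = NicheModelConfig(n_background=1500, seed=0)


def occ_from_cells(stack, cells, group="g"):
    pts = np.array([stack.cell_center(r, c) for r, c in cells])
    return OccurrenceSet(group=group, points=pts)


class TestBackgroundSampling:
    def test_exact_cell_set_when_n_exceeds_cells(self, landscape):
        cells = sample_background_points(landscape, n=10**7, seed=0)
        assert len(cells) == len(landscape.valid_cells())

    def test_nodata_never_sampled(self):
        g = np.ones((30, 30))
        g[:15] = -9999.0
        st = EnvStack({"v": g}, 1.0, 0.0, 0.0)
        cells = sample_background_points(st, 200, seed=1)
        assert (cells[:, 0] >= 15).all()

    def test_seed_determinism(self, landscape):
        a = sample_background_points(landscape, 100, seed=3)
        b = sample_background_points(landscape, 100, seed=3)
        np.testing.assert_array_equal(a, b)


class TestPruning:
    def test_duplicated_variable_dropped(self, landscape):
        st = EnvStack(
            {
                "a": landscape.variables["bio_1"],
                "b": landscape.variables["bio_1"].copy(),
                "c": landscape.variables["bio_12"],
            },
            landscape.cell_size,
            landscape.origin_x,
            landscape.origin_y,
        )
        pts = sample_background_points(st, 2000, seed=0)
        kept = prune_correlated_variables(st, pts)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_independent_variables_retained(self, landscape):
        pts = sample_background_points(landscape, 2000, seed=0)
        kept = prune_correlated_variables(landscape, pts)
        assert kept == landscape.variable_names

    def test_planted_collinear_pair(self, landscape):
        noisy = landscape.variables["bio_7"] * 1.3 + 0.5
        st = EnvStack(
            {**landscape.variables, "bio_7_scaled": noisy},
            landscape.cell_size,
            landscape.origin_x,
            landscape.origin_y,
        )
        pts = sample_background_points(st, 2000, seed=0)
        kept = prune_correlated_variables(st, pts)
        assert len(kept) == 3
        assert len([k for k in kept if k.startswith("bio_7")]) == 1


class TestMaxentLite:
    def test_uniform_occurrences_yield_null_model(self, landscape):
        rng = np.random.default_rng(1)
        cells = landscape.valid_cells()
        occ = occ_from_cells(
            landscape, cells[rng.choice(len(cells), 400, replace=False)]
        )
        model = fit_maxent_lite(landscape, occ, CFG)
        # weights stay near zero (sampling noise only) and AUC near chance
        assert np.abs(model.weights).max() < 0.15
        assert model.train_auc < 0.6

    def test_monotone_response_sign(self, landscape):
        v = landscape.variables["bio_1"]
        cells = landscape.valid_cells()
        vals = v[cells[:, 0], cells[:, 1]]
        hot = cells[vals > np.quantile(vals, 0.8)]
        occ = occ_from_cells(landscape, hot)
        model = fit_maxent_lite(landscape, occ, CFG)
        assert model.weights[model.feature_names.index("bio_1")] > 0
        assert model.train_auc > 0.8

    def test_gaussian_optimum_recovery(self, landscape):
        """Occurrences from a Gaussian response on bio_1: the fitted
        quadratic recovers the optimum within 0.25 climatic SD."""
        rng = np.random.default_rng(2)
        cells = landscape.valid_cells()
        v = landscape.variables["bio_1"][cells[:, 0], cells[:, 1]]
        sd_all = v.std()
        opt_true = v.mean() + 0.5 * sd_all
        w = np.exp(-0.5 * ((v - opt_true) / (0.8 * sd_all)) ** 2)
        pick = rng.choice(len(cells), size=500, p=w / w.sum())
        occ = occ_from_cells(landscape, cells[pick])
        model = fit_maxent_lite(landscape, occ, CFG)
        i_lin = model.feature_names.index("bio_1")
        i_quad = model.feature_names.index("bio_1^2")
        b1 = model.weights[i_lin] / model.feature_sd[i_lin]
        b2 = model.weights[i_quad] / model.feature_sd[i_quad]
        assert b2 < 0  # concave response
        mu = model.feature_mean[i_lin]
        opt_est = mu + b1 / (-2 * b2)
        assert abs(opt_est - opt_true) < 0.25 * sd_all

    def test_too_few_presences_rejected(self, landscape):
        occ = occ_from_cells(landscape, landscape.valid_cells()[:3])
        with pytest.raises(ValueError, match="presence"):
            fit_maxent_lite(landscape, occ, CFG)

    def test_q_is_distribution(self, landscape):
        sc = NicheScenario.preset("displaced", landscape, n_points=(200, 200))
        occ = make_occurrence_scenario(landscape, sc, seed=3)["group_a"]
        model = fit_maxent_lite(landscape, occ, CFG)
        assert model.q_background.min() >= 0
        assert model.q_background.sum() == pytest.approx(1.0)
        assert model.entropy > 0


class TestAUC:
    def test_brute_force_pair_counting(self, landscape):
        # hand fixture: presence scores {2, 4}, background {1, 3, 3}
        class Dummy:
            def raw_scores(self, stack, cells):
                flat = cells[:, 0]
                return flat.astype(float)

        presence = np.array([[2, 0], [4, 0]])
        background = np.array([[1, 0], [3, 0], [3, 0]])
        # pairs: (2>1), (2<3), (2<3) / (4>1), (4>3), (4>3) -> 4 wins of 6
        auc = auc_presence_background(Dummy(), landscape, presence, background)
        assert auc == pytest.approx(4 / 6)

    def test_separated_and_identical(self, landscape):
        class Up:
            def raw_scores(self, stack, cells):
                return cells[:, 0].astype(float)

        pres = np.array([[10, 0], [11, 0]])
        bg = np.array([[1, 0], [2, 0]])
        assert auc_presence_background(Up(), landscape, pres, bg) == 1.0

        class Flat:
            def raw_scores(self, stack, cells):
                return np.zeros(len(cells))

        assert auc_presence_background(Flat(), landscape, pres, bg) == 0.5


class TestModelGrid:
    def test_grid_report_shape_and_tau_invariance(self, landscape):
        sc = NicheScenario.preset("displaced", landscape, n_points=(150, 150))
        occ = make_occurrence_scenario(landscape, sc, seed=4)["group_a"]
        best, report = select_model_grid(
            landscape, occ, tau_grid=(0.5, 0.7), beta_grid=(1.0, 2.0), seed=5,
            base_config=CFG,
        )
        assert len(report) == 4
        # AUC is invariant to tau (monotone rescale): per-beta AUCs match
        for beta in (1.0, 2.0):
            aucs = report[report.beta == beta]["auc"]
            assert aucs.max() - aucs.min() < 1e-12
        # ties resolve to the smallest beta / tau among the best
        top = report[report.auc == report.auc.max()]
        assert best.config.beta == top.beta.min()

    def test_single_cell_grid(self, landscape):
        sc = NicheScenario.preset("identical", landscape, n_points=(100, 100))
        occ = make_occurrence_scenario(landscape, sc, seed=6)["group_a"]
        best, report = select_model_grid(
            landscape, occ, tau_grid=(0.6,), beta_grid=(2.0,), seed=7, base_config=CFG
        )
        assert len(report) == 1
        assert best.config.tau == 0.6 and best.config.beta == 2.0


class TestOverlap:
    def test_identical_surfaces_give_one(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        d, i = overlap_stats(p, p.copy())
        assert d == 1.0 and i == 1.0

    def test_disjoint_supports_give_zero(self):
        x = np.array([0.5, 0.5, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.25, 0.75])
        d, i = overlap_stats(x, y)
        assert d == 0.0
        assert i == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_hand_value(self):
        d, i = overlap_stats(np.array([0.7, 0.3]), np.array([0.3, 0.7]))
        assert d == pytest.approx(0.6)
        assert i == pytest.approx(1 - (np.sqrt(0.7) - np.sqrt(0.3)) ** 2)

    def test_invariance_to_common_scaling_and_order(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        y = rng.random(50)
        d1, i1 = overlap_stats(x, y)
        d2, i2 = overlap_stats(7.3 * x, 7.3 * y)
        assert (d1, i1) == pytest.approx((d2, i2))
        perm = rng.permutation(50)
        d3, i3 = overlap_stats(x[perm], y[perm])
        assert (d1, i1) == pytest.approx((d3, i3))

    def test_displaced_scenario_low_overlap(self, landscape):
        """Optima 4 SD apart leave Schoener's D below 0.5 (5-seed median)."""
        ds = []
        for seed in range(5):
            sc = NicheScenario.preset("displaced", landscape, n_points=(250, 250))
            occ = make_occurrence_scenario(landscape, sc, seed=seed)
            ma = fit_maxent_lite(landscape, occ["group_a"], CFG)
            mb = fit_maxent_lite(landscape, occ["group_b"], CFG)
            d, _ = model_overlap(ma, mb, landscape, landscape.valid_cells())
            ds.append(d)
        assert np.median(ds) < 0.5


class TestIdentityTest:
    def test_same_points_not_significant(self, landscape):
        sc = NicheScenario.preset("identical", landscape, n_points=(120, 120))
        occ = make_occurrence_scenario(landscape, sc, seed=8)
        same = OccurrenceSet("copy", occ["group_a"].points.copy())
        res = identity_test(
            landscape, occ["group_a"], same, CFG, n_reps=50, seed=9
        )
        assert res.verdict_d == "not_significant"
        assert res.d_observed >= np.quantile(res.null_d, 0.5)

    def test_displaced_niches_detected(self, landscape):
        sc = NicheScenario.preset("displaced", landscape, n_points=(200, 200))
        occ = make_occurrence_scenario(landscape, sc, seed=10)
        res = identity_test(
            landscape, occ["group_a"], occ["group_b"], CFG, n_reps=100, seed=11
        )
        assert res.p_d < 0.01 and res.p_i < 0.01
        assert res.verdict_d == res.verdict_i == "not_identical"
        assert len(res.null_d) == 100


class TestBackgroundSimilarity:
    def test_uniform_draws_not_significant(self, landscape):
        """occ_y drawn uniformly from its region reproduces the null."""
        rng = np.random.default_rng(12)
        cells = landscape.valid_cells()
        occ_x = occ_from_cells(
            landscape, cells[rng.choice(len(cells), 150, replace=False)], "x"
        )
        occ_y = occ_from_cells(
            landscape, cells[rng.choice(len(cells), 120, replace=False)], "y"
        )
        x1 = landscape.origin_x + landscape.n_cols * landscape.cell_size
        y1 = landscape.origin_y + landscape.n_rows * landscape.cell_size
        res = background_similarity_test(
            landscape,
            occ_x,
            occ_y,
            region_y=(0.0, x1, 0.0, y1),
            config=CFG,
            n_reps=60,
            seed=13,
        )
        assert res.verdict_i == "not_significant"

    def test_displaced_scenario_divergence(self, landscape):
        sc = NicheScenario.preset("displaced", landscape, n_points=(220, 220))
        occ = make_occurrence_scenario(landscape, sc, seed=14)
        x1 = landscape.origin_x + landscape.n_cols * landscape.cell_size
        y1 = landscape.origin_y + landscape.n_rows * landscape.cell_size
        res = background_similarity_test(
            landscape,
            occ["group_a"],
            occ["group_b"],
            region_y=(0.0, x1, 0.0, y1),
            config=CFG,
            n_reps=60,
            seed=15,
        )
        assert res.verdict_i == "divergence"

    def test_identical_shared_niche_never_divergence(self, landscape):
        """Identical niches in disjoint regions: conservatism or n.s."""
        verdicts = []
        for seed in range(4):
            sc = NicheScenario.preset(
                "background_driven", landscape, n_points=(120, 120)
            )
            # same optimum, narrow breadth: both groups track the shared
            # niche inside their own background
            for g in sc.groups.values():
                g.breadth = {k: v / 3 for k, v in g.breadth.items()}
            occ = make_occurrence_scenario(landscape, sc, seed=20 + seed)
            res = background_similarity_test(
                landscape,
                occ["group_a"],
                occ["group_b"],
                config=CFG,
                n_reps=40,
                seed=30 + seed,
            )
            verdicts.append(res.verdict_i)
        assert "divergence" not in verdicts

    def test_region_too_small_rejected(self, landscape):
        sc = NicheScenario.preset("identical", landscape, n_points=(120, 120))
        occ = make_occurrence_scenario(landscape, sc, seed=16)
        with pytest.raises(ValueError, match="region"):
            background_similarity_test(
                landscape,
                occ["group_a"],
                occ["group_b"],
                region_y=(0.0, 1.0, 0.0, 1.0),
                config=CFG,
                n_reps=10,
                seed=17,
            )
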