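"""The synthetic orchard generator: determinism, ground-truth bookkeeping,
pruning/growth events and scan perturbation."""

import numpy as np
import pytest

from shootdelta import (TreeSpec, generate_tree, ks_normality, make_triple,
                        perturb_scan, simulate_growth, simulate_prune,
                        transform_values)
from shootdelta.exceptions import SpecError
from shootdelta.synthetic import (_arc_centerline, _draw_angle, _draw_length,
                                  _orthonormal_to)


class TestArcCenterline:
    """The circular-arc primitive underlying every ground-truth length."""

    @pytest.mark.parametrize("arc_len,bow", [(0.3, 0.0), (0.5, 0.05),
                                             (0.8, 0.2), (0.2, 0.3)])
    def test_exact_arc_length_and_chord_direction(self, arc_len, bow):
        u = np.array([0.6, 0.0, 0.8])
        w = _orthonormal_to(u, 0.3)
        attach = np.array([1.0, 2.0, 3.0])
        centers, tangents, s_frac = _arc_centerline(
            attach, u, w, arc_len, bow, spacing=1e-4)
        seg = np.linalg.norm(np.diff(centers, axis=0), axis=1).sum()
        assert seg == pytest.approx(arc_len, rel=1e-6)
        chord = centers[-1] - centers[0]
        np.testing.assert_allclose(chord / np.linalg.norm(chord), u, atol=1e-9)
        assert s_frac[0] == 0.0 and s_frac[-1] == 1.0

    def test_bow_height(self):
        u = np.array([1.0, 0, 0])
        w = np.array([0.0, 1.0, 0])
        arc_len, bow = 0.4, 0.1
        centers, _, _ = _arc_centerline(np.zeros(3), u, w, arc_len, bow, 1e-4)
        assert centers[:, 1].max() == pytest.approx(bow * arc_len, rel=1e-3)


class TestGenerateTree:
    def test_no_shoots_only_wood(self):
        cloud, truth = generate_tree(TreeSpec(seed=1, n_shoots=0,
                                              point_spacing=0.01))
        assert set(np.unique(cloud.labels["organ"])) == {"trunk", "scaffold"}
        assert len(truth.shoots) == 0

    def test_shoot_count_and_chord_angle(self):
        spec = TreeSpec(seed=5, n_shoots=25, point_spacing=0.008)
        cloud, truth = generate_tree(spec)
        sids = np.unique(cloud.labels["shoot_id"])
        assert len(sids[sids >= 0]) == 25
        assert len(truth.shoots) == 25
        assert ((truth.shoots["true_angle"] > 0)
                & (truth.shoots["true_angle"] <= 90)).all()
        assert (truth.shoots["true_length"] > 0).all()

    def test_determinism(self):
        spec = TreeSpec(seed=9, n_shoots=10, point_spacing=0.01)
        a, ta = generate_tree(spec)
        b, tb = generate_tree(spec)
        np.testing.assert_array_equal(a.points, b.points)
        assert ta.shoots.equals(tb.shoots)

    def test_architectures_scaffold_counts(self):
        for arch, n_scaf in (("Y", 2), ("two_plus_one", 3),
                             ("three_plus_one", 4)):
            spec = TreeSpec(architecture=arch, seed=2, n_shoots=0,
                            point_spacing=0.02)
            cloud, _ = generate_tree(spec)
            assert (cloud.labels["organ"] == "scaffold").sum() > 0
        with pytest.raises(SpecError):
            generate_tree(TreeSpec(architecture="bonsai"))

    def test_per_point_and_per_shoot_ids_consistent(self, small_tree):
        _, cloud, truth = small_tree
        point_sids = set(np.unique(cloud.labels["shoot_id"]).tolist()) - {-1}
        table_sids = set(truth.shoots["shoot_id"].tolist())
        assert point_sids == table_sids


class TestDistributionModels:
    def test_length_draws_lognormal_on_transformed_scale(self):
        passed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            draws = np.array([_draw_length(rng, (-0.33, 0.25))
                              for _ in range(5000)])
            p = ks_normality(transform_values(draws, "log10_offset"))
            passed += p > 0.05
        assert passed >= 9

    def test_angle_draws_normal_on_sqrt_scale(self):
        # model with negligible truncation mass at the 90° cap
        passed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            draws = np.array([_draw_angle(rng, (8.0, 0.5))
                              for _ in range(5000)])
            p = ks_normality(transform_values(draws, "sqrt"))
            passed += p > 0.05
        assert passed >= 9

    def test_angle_draws_bounded(self):
        rng = np.random.default_rng(0)
        draws = [_draw_angle(rng, (8.67, 1.2)) for _ in range(2000)]
        assert 0 < min(draws) and max(draws) <= 90


@pytest.fixture(scope="module")
def tree():
    spec = TreeSpec(seed=21, n_shoots=25, point_spacing=0.008)
    return generate_tree(spec)


class TestSimulatePrune:
    def test_zero_fraction_identity(self, tree):
        cloud, truth = tree
        out, _ = simulate_prune(cloud.copy(), truth.copy(), 0.0, seed=1)
        assert len(out) == len(cloud)

    def test_full_thinning_removes_all_shoots(self, tree):
        cloud, truth = tree
        out, out_truth = simulate_prune(cloud.copy(), truth.copy(), 1.0,
                                        thinning_fraction=1.0, seed=1)
        assert (out.labels["organ"] != "shoot").all()
        assert len(out_truth.shoots) == 0

    def test_realized_fraction(self):
        fracs = []
        for seed in range(20):
            spec = TreeSpec(seed=seed, n_shoots=25, point_spacing=0.015)
            cloud, truth = generate_tree(spec)
            _, out_truth = simulate_prune(cloud, truth, 0.8,
                                          thinning_fraction=1.0, seed=seed)
            fracs.append(1 - len(out_truth.shoots) / 25)
        assert abs(np.mean(fracs) - 0.8) <= 0.02

    def test_angle_bias_prefers_steep_shoots(self, tree):
        cloud, truth = tree
        c, t = cloud.copy(), truth.copy()
        simulate_prune(c, t, 0.5, angle_bias=0.5, seed=3)
        shoots = t.shoots
        pruned = shoots[shoots["status"] == "pruned"]["true_angle"]
        kept = shoots[shoots["status"] != "pruned"]["true_angle"]
        assert pruned.mean() > kept.mean()

    def test_marks_pre_event_status(self, tree):
        cloud, truth = tree
        c, t = cloud.copy(), truth.copy()
        simulate_prune(c, t, 0.6, thinning_fraction=1.0, seed=4)
        assert (c.labels["status"] == "pruned").sum() > 0


class TestSimulateGrowth:
    def test_zero_identity(self, small_tree):
        spec, cloud, truth = small_tree
        out, _ = simulate_growth(cloud, truth, spec, 0, seed=1)
        assert len(out) == len(cloud)

    def test_adds_annual_shoots(self, small_tree):
        spec, cloud, truth = small_tree
        out, out_truth = simulate_growth(cloud, truth, spec, 12, seed=1)
        new = out_truth.shoots[out_truth.shoots["status"] == "annual"]
        assert len(new) == 12
        assert (out.labels["status"] == "annual").sum() > 0
        # pre-existing points untouched, ids unique
        np.testing.assert_array_equal(out.points[:len(cloud)], cloud.points)
        assert len(np.unique(out.ids)) == len(out)


class TestPerturbScan:
    def test_zero_parameters_identity(self, small_tree):
        _, cloud, _ = small_tree
        out, t = perturb_scan(cloud)
        np.testing.assert_array_equal(out.points, cloud.points)
        np.testing.assert_allclose(t.rotation, np.eye(3))

    def test_known_transform_applied(self, small_tree):
        _, cloud, _ = small_tree
        out, t = perturb_scan(cloud, yaw_deg=3.0, translation=(1, -2, 0.5))
        np.testing.assert_allclose(out.points, t.apply(cloud.points))

    def test_dropout_count(self, small_tree):
        _, cloud, _ = small_tree
        out, _ = perturb_scan(cloud, noise_sigma=0.003, dropout=0.1, seed=2)
        assert len(out) == int(np.ceil(0.9 * len(cloud)))
        assert set(out.ids) <= set(cloud.ids)


class TestMakeTriple:
    def test_no_growth_no_prune_gives_empty_truth_sets(self):
        spec = TreeSpec(seed=31, n_shoots=10, point_spacing=0.01)
        tr = make_triple(spec, growth={"n_new": 0},
                         prune2={"target_fraction": 0.0}, seed=31)
        assert len(tr.true_as_ids) == 0
        assert len(tr.true_ps_ids) == 0

    def test_manifest_truth_bookkeeping(self):
        spec = TreeSpec(seed=32, n_shoots=10, point_spacing=0.01)
        tr = make_triple(spec, seed=32)
        # AS truth = exactly the annual-status shoot ids present in the scan
        sid = tr.bp_next.labels["shoot_id"]
        annual_sids = set(
            tr.truth_bp_next.shoots["shoot_id"]) - set(
            tr.truth_ap_i.shoots["shoot_id"])
        expect = tr.bp_next.ids[np.isin(sid, sorted(annual_sids))]
        np.testing.assert_array_equal(tr.true_as_ids, np.sort(expect))
        assert tr.manifest["true_as_ids"] == tr.true_as_ids.tolist()

    def test_deterministic(self):
        spec = TreeSpec(seed=33, n_shoots=8, point_spacing=0.012)
        a = make_triple(spec, seed=33)
        b = make_triple(spec, seed=33)
        np.testing.assert_array_equal(a.bp_next.points, b.bp_next.points)
        np.testing.assert_array_equal(a.true_ps_ids, b.true_ps_ids)
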