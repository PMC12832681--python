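"""Counterfactual engine: unit closed forms, optimization, sparsification."""

import numpy as np
import pytest

import fcexplain as fx
from fcexplain.counterfactual import MAD_FLOOR


class TestMAD:
    def test_textbook_column(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        assert fx.compute_mads(X).values[0] == 1.0

    def test_symmetric_column(self):
        a = 0.7
        X = np.array([[-a], [0.0], [a]])
        assert fx.compute_mads(X).values[0] == pytest.approx(a)

    def test_constant_column_floored_with_warning(self, caplog):
        X = np.ones((5, 2))
        mads = fx.compute_mads(X)
        assert np.all(mads.values == MAD_FLOOR)
        assert "floored" in caplog.text


class TestHinge:
    @pytest.mark.parametrize(
        "logit,target,expected",
        [(2.0, 1, 0.0), (0.5, 1, 0.5), (-3.0, 0, 0.0), (1.0, 0, 2.0),
         (-1.0, 1, 2.0)],
    )
    def test_closed_form(self, logit, target, expected):
        assert fx.hinge_loss(logit, target) == pytest.approx(expected)


class TestMadDistance:
    def setup_method(self):
        self.mads = fx.MADVector(values=np.array([0.5, 0.5, 0.5, 0.5]))

    def test_identity_is_zero(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert fx.mad_distance(x, x, self.mads) == 0.0

    def test_single_feature_one_mad(self):
        m = np.zeros(4)
        x = m.copy()
        x[2] = 0.5  # exactly one MAD on one of four features
        assert fx.mad_distance(x, m, self.mads) == pytest.approx(0.25)

    def test_symmetry(self, rng):
        x, m = rng.normal(size=4), rng.normal(size=4)
        assert fx.mad_distance(x, m, self.mads) == fx.mad_distance(m, x, self.mads)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fx.mad_distance(np.zeros(3), np.zeros(4), self.mads)


class TestDiversityDet:
    def setup_method(self):
        self.mads = fx.MADVector(values=np.array([0.25, 0.25]))

    def test_identical_candidates_rank_deficient(self):
        C = np.array([[0.1, 0.2], [0.1, 0.2]])
        assert fx.diversity_det(C, self.mads) == pytest.approx(0.0, abs=1e-12)

    def test_unit_distance_pair(self):
        # pairwise MAD distance exactly 1 -> K = [[1, .5], [.5, 1]], det .75
        C = np.array([[0.0, 0.0], [0.25, 0.25]])
        assert fx.mad_distance(C[0], C[1], self.mads) == pytest.approx(1.0)
        assert fx.diversity_det(C, self.mads) == pytest.approx(0.75)

    def test_single_candidate_unit_det(self):
        assert fx.diversity_det(np.array([[0.3, 0.4]]), self.mads) == 1.0

    def test_far_candidates_approach_one(self):
        C = np.array([[-1.0, -1.0], [1.0, 1.0]])
        assert 0.9 < fx.diversity_det(C, self.mads) <= 1.0

    def test_jitter_bounded_and_seeded(self):
        C = np.array([[0.0, 0.0], [0.25, 0.25]])
        a = fx.diversity_det(C, self.mads, jitter_scale=1e-4, seed=5)
        b = fx.diversity_det(C, self.mads, jitter_scale=1e-4, seed=5)
        assert a == b
        assert abs(a - 0.75) < 3e-4  # perturbation of order jitter


# toy geometry where crossing the boundary is worth the proximity cost:
# logit = x1 + x2, MADs 0.4 -> hinge benefit per coordinate 1/L exceeds
# gamma1 / (L * q * MAD) = gamma1 * 1.25 / L for gamma1 <= 0.5
TOY_MADS = fx.MADVector(values=np.array([0.4, 0.4]))
TOY_M = np.array([-0.5, -0.5])  # logit -1, predicted patient


class TestGenerate:
    def test_pure_hinge_reaches_zero_loss(self, toy_model):
        cfg = fx.CFConfig(L=3, gamma1=0.0, gamma2=0.0, seed=0)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        assert cf.n_valid == 3
        logits = toy_model.logit(cf.candidates)
        assert np.all(fx.hinge_loss(logits, 1) < 1e-3)

    def test_validity_flags_match_predictions(self, toy_model):
        cfg = fx.CFConfig(L=5, seed=1)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        np.testing.assert_array_equal(
            cf.validity, toy_model.predict(cf.candidates) == 1
        )

    def test_candidates_respect_box_bounds(self, toy_model):
        cfg = fx.CFConfig(L=5, seed=2, learning_rate=0.3)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        assert cf.candidates.min() >= -1.0 and cf.candidates.max() <= 1.0

    def test_objective_non_increasing(self, toy_model):
        cfg = fx.CFConfig(L=4, seed=3)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        trace = np.array(cf.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_proximity_improves_with_gamma1(self, toy_model):
        def mean_dist(g1):
            cfg = fx.CFConfig(L=4, gamma1=g1, gamma2=0.0, seed=7)
            cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
            assert cf.n_valid == 4
            return np.mean([
                fx.mad_distance(c, TOY_M, TOY_MADS) for c in cf.candidates
            ])

        assert mean_dist(0.5) < mean_dist(0.0)

    def test_diversity_improves_with_gamma2(self, toy_model):
        def mean_pairwise(g2):
            cfg = fx.CFConfig(L=4, gamma1=0.5, gamma2=g2, seed=7)
            cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
            C = cf.candidates
            return np.mean([
                fx.mad_distance(C[u], C[v], TOY_MADS)
                for u in range(4) for v in range(u + 1, 4)
            ])

        assert mean_pairwise(1.0) > mean_pairwise(0.0)

    def test_deterministic_full_chain(self, toy_model):
        cfg = fx.CFConfig(L=5, seed=11)
        a = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        b = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        np.testing.assert_array_equal(a.candidates, b.candidates)
        sa = fx.sparsify(a, toy_model)
        sb = fx.sparsify(b, toy_model)
        np.testing.assert_array_equal(sa.candidates, sb.candidates)
        assert fx.diff_report(sa, ("e1", "e2")) == fx.diff_report(sb, ("e1", "e2"))

    def test_zero_valid_reported_not_raised(self, toy_model, caplog):
        # proximity so expensive that staying put is optimal
        cfg = fx.CFConfig(L=2, gamma1=50.0, gamma2=0.0, seed=0, max_iters=50)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        assert cf.n_valid == 0
        assert "no valid counterfactual" in caplog.text

    def test_out_of_bounds_original_rejected(self, toy_model):
        with pytest.raises(ValueError, match="bounds"):
            fx.generate_counterfactuals(
                toy_model, np.array([2.0, 0.0]), fx.CFConfig(), mads=TOY_MADS
            )


class TestSparsify:
    def test_redundant_change_restored(self, toy_model):
        cf = fx.CounterfactualSet(
            original=TOY_M.copy(),
            candidates=np.array([[0.7, -0.45]]),  # logit 0.25; tiny 2nd change
            validity=np.array([True]),
            target_label=1,
            objective_trace=[],
            mads=TOY_MADS,
        )
        out = fx.sparsify(cf, toy_model)
        assert out.candidates[0, 1] == TOY_M[1]  # redundant edge restored
        assert out.validity[0]

    def test_necessary_changes_kept(self, toy_model):
        cf = fx.CounterfactualSet(
            original=TOY_M.copy(),
            candidates=np.array([[0.3, 0.2]]),  # logit 0.5; both needed
            validity=np.array([True]),
            target_label=1,
            objective_trace=[],
            mads=TOY_MADS,
        )
        out = fx.sparsify(cf, toy_model)
        np.testing.assert_array_equal(out.candidates, cf.candidates)

    def test_weakly_fewer_changes_and_validity_preserved(self, toy_model):
        cfg = fx.CFConfig(L=5, seed=4)
        cf = fx.generate_counterfactuals(toy_model, TOY_M, cfg, mads=TOY_MADS)
        out = fx.sparsify(cf, toy_model)
        for l in range(5):
            before = len(cf.diffs(l))
            after = len(out.diffs(l))
            assert after <= before
            if cf.validity[l]:
                assert out.validity[l]


def test_sparsified_counterfactuals_touch_few_edges():
    """Full-pipeline counterfactuals on 4-feature models: after greedy
    sparsification the median number of changed edges is at most 2."""
    counts = []
    for seed in range(5):
        sig = (0, 7, 14, 21)
        spec = fx.SyntheticSpec(seed=seed, effect_size=2.0, n_per_class=60,
                                signal_edges=sig)
        ds = fx.generate_fc_dataset(spec)
        s = fx.generate_penalty_scores(ds.edge_map, sig, "informative", seed)
        sel = fx.select_transform_cv(ds.X, ds.Y, s, seed=seed)
        fit = fx.fit_selected(ds.X, ds.Y, sel)
        selected = fx.select_features(fit)[:4]
        Xq = ds.X[:, selected]
        model = fx.train_margin_classifier(Xq, ds.Y)
        mads = fx.compute_mads(Xq)
        patients = np.flatnonzero((ds.Y == 0) & (model.predict(Xq) == 0))[:5]
        for i, subj in enumerate(patients):
            cf = fx.sparsify(
                fx.generate_counterfactuals(
                    model, Xq[subj], fx.CFConfig(L=5, seed=seed + i), mads=mads
                ),
                model,
            )
            counts += [len(cf.diffs(l)) for l in range(5) if cf.validity[l]]
    assert len(counts) >= 100  # most candidates valid
    assert np.median(counts) <= 2


class TestDiffReport:
    def test_direction_and_magnitude_formatting(self, toy_model):
        cf = fx.CounterfactualSet(
            original=np.array([-0.359, 0.5]),
            candidates=np.array([[0.431, 0.5]]),
            validity=np.array([True]),
            target_label=1,
            objective_trace=[],
            mads=TOY_MADS,
        )
        report = fx.diff_report(cf, ("CAU.L-AMYG.R", "PCL.L-IOG.L"))
        assert "increase" in report and "+0.790" in report
        assert "PCL.L-IOG.L" not in report  # unchanged edge absent

    def test_unchanged_candidate_empty_diffs(self):
        cf = fx.CounterfactualSet(
            original=TOY_M.copy(),
            candidates=TOY_M.copy()[None, :],
            validity=np.array([False]),
            target_label=1,
            objective_trace=[],
            mads=TOY_MADS,
        )
        assert "(no change)" in fx.diff_report(cf, ("a", "b"))
        assert cf.diffs(0) == []

    def test_diffs_sorted_by_normalized_magnitude(self):
        mads = fx.MADVector(values=np.array([0.1, 1.0]))
        cf = fx.CounterfactualSet(
            original=np.zeros(2),
            candidates=np.array([[0.2, 0.5]]),  # |d|/MAD: 2.0 vs 0.5
            validity=np.array([True]),
            target_label=1,
            objective_trace=[],
            mads=mads,
        )
        assert [j for j, _, _ in cf.diffs(0)] == [0, 1]
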