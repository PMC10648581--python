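"""AUC, the ridge-logistic scorer, cross-validation, and forward selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirec import (
    GroupContrast,
    SfsConfig,
    build_subtype_models,
    cv_pooled_auc,
    fit_linear_scorer,
    repeated_cv_auc,
    roc_auc,
    sequential_forward_select,
)
from mirec.classify import UndefinedAucError

from conftest import expr_matrix, two_group_annotations


def contrast_for(n_pos, n_neg):
    ids = [f"s{j}" for j in range(n_pos + n_neg)]
    return GroupContrast("test", tuple(ids[:n_pos]), tuple(ids[n_pos:]))


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_boundaries(self):
        assert roc_auc([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0]) == 1.0
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_score_negation_complements_auc_without_ties(self):
        rng = np.random.default_rng(2)
        scores = rng.permutation(40).astype(float)  # distinct scores
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(UndefinedAucError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


class TestLinearScorer:
    def test_separable_feature_gives_training_auc_one(self):
        vals = np.zeros((1, 20))
        vals[0, :10] = 3.0  # planted 8x effect, no noise
        expr = expr_matrix(vals)
        c = contrast_for(10, 10)
        scorer = fit_linear_scorer(expr, c, ["m0"])
        scores = scorer.score(expr, list(c.positive_ids) + list(c.negative_ids))
        assert roc_auc(scores, [1] * 10 + [0] * 10) == 1.0

    def test_weight_sign_tracks_planted_direction(self):
        signs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 1, (1, 40))
            vals[0, :20] += 2.0
            scorer = fit_linear_scorer(expr_matrix(vals), contrast_for(20, 20), ["m0"])
            signs.append(scorer.weights[0] > 0)
        assert all(signs)

    def test_constant_feature_gets_zero_weight(self, caplog):
        rng = np.random.default_rng(0)
        vals = np.vstack([np.full(30, 7.0), rng.normal(0, 1, 30)])
        vals[1, :15] += 2.0
        with caplog.at_level("WARNING"):
            scorer = fit_linear_scorer(expr_matrix(vals), contrast_for(15, 15), ["m0", "m1"])
        assert scorer.weights[0] == 0.0
        assert scorer.weights[1] != 0.0
        assert "constant" in caplog.text


class TestCrossValidation:
    def test_same_fold_seed_reproduces_auc(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (3, 60))
        vals[0, :25] += 1.0
        expr = expr_matrix(vals)
        c = contrast_for(25, 35)
        cfg = SfsConfig(seed=0)
        a = cv_pooled_auc(expr, c, ["m0", "m1"], cfg, fold_seed=17)
        b = cv_pooled_auc(expr, c, ["m0", "m1"], cfg, fold_seed=17)
        assert a == b

    def test_strong_feature_reaches_high_auc(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1.0, (1, 102))
        vals[0, :48] += 3.0  # 8-fold planted effect, 48 vs 54
        expr = expr_matrix(vals)
        auc = cv_pooled_auc(expr, contrast_for(48, 54), ["m0"], SfsConfig(seed=0), 5)
        assert auc > 0.9

    @pytest.mark.parametrize("n_features", [1, 5, 10])
    def test_pure_noise_stays_in_null_band(self, n_features):
        # guards against information leak from test folds into the scorer
        rng = np.random.default_rng(40 + n_features)
        vals = rng.normal(0, 1.0, (n_features, 102))
        expr = expr_matrix(vals)
        cfg = SfsConfig(seed=1)
        aucs = repeated_cv_auc(
            expr, contrast_for(48, 54), list(expr.mirna_ids), cfg, cfg.evaluation_seeds()[:10]
        )
        assert 0.35 < float(np.mean(aucs)) < 0.65

    def test_shuffled_labels_stay_in_null_band(self):
        rng = np.random.default_rng(7)
        n = 300
        vals = rng.normal(0, 1.0, (4, n))
        vals[:, : n // 2] += 1.5  # real structure...
        perm = rng.permutation(n)  # ...destroyed by shuffling the labels
        expr = expr_matrix(vals[:, perm])
        auc = cv_pooled_auc(
            expr, contrast_for(n // 2, n // 2), list(expr.mirna_ids), SfsConfig(seed=2), 3
        )
        assert 0.35 < auc < 0.65

    def test_class_smaller_than_n_folds_advises_fewer_folds(self):
        rng = np.random.default_rng(8)
        expr = expr_matrix(rng.normal(size=(1, 12)))
        with pytest.raises(Exception, match="n_folds"):
            cv_pooled_auc(expr, contrast_for(3, 9), ["m0"], SfsConfig(n_folds=5), 0)


class TestForwardSelection:
    def small_config(self, **kw):
        base = dict(n_folds=5, n_repeats=5, n_selection_repeats=3, seed=1)
        base.update(kw)
        return SfsConfig(**base)

    def test_informative_feature_selected_first(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1.0, (20, 80))
        vals[7, :40] += 3.0
        expr = expr_matrix(vals)
        model = sequential_forward_select(
            expr, contrast_for(40, 40), list(expr.mirna_ids), self.small_config(max_features=3)
        )
        assert model.selected_mirnas[0] == "m7"

    def test_trace_is_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1.0, (15, 70))
        vals[2, :30] += 1.5
        vals[9, :30] += 1.5
        expr = expr_matrix(vals)
        cfg = self.small_config(max_features=4)
        model = sequential_forward_select(expr, contrast_for(30, 40), list(expr.mirna_ids), cfg)
        crits = [c for _, c in model.selection_trace]
        assert crits == sorted(crits)
        assert 1 <= len(model.selected_mirnas) <= 4
        assert model.mean_auc == pytest.approx(float(np.mean(model.repeat_aucs)))

    def test_rerun_is_bit_identical(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1.0, (10, 60))
        vals[4, :25] += 2.0
        expr = expr_matrix(vals)
        cfg = self.small_config(max_features=2)
        c = contrast_for(25, 35)
        m1 = sequential_forward_select(expr, c, list(expr.mirna_ids), cfg)
        m2 = sequential_forward_select(expr, c, list(expr.mirna_ids), cfg)
        assert m1.to_dict() == m2.to_dict()

    def test_all_constant_candidates_fall_back_to_single_feature(self, caplog):
        expr = expr_matrix(np.full((4, 40), 2.5))
        with caplog.at_level("WARNING"):
            model = sequential_forward_select(
                expr, contrast_for(20, 20), list(expr.mirna_ids), self.small_config()
            )
        assert len(model.selected_mirnas) == 1
        assert model.mean_auc == pytest.approx(0.5)

    def test_model_beats_single_features_with_independent_effects(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0, 1.0, (30, 102))
        planted = ["m3", "m11", "m22"]
        for m in planted:
            vals[int(m[1:]), :48] += 1.2
        expr = expr_matrix(vals)
        c = contrast_for(48, 54)
        cfg = self.small_config(max_features=5)
        model = sequential_forward_select(expr, c, list(expr.mirna_ids), cfg)
        assert set(planted) <= set(model.selected_mirnas)
        singles = [
            float(np.mean(repeated_cv_auc(expr, c, [m], cfg, cfg.evaluation_seeds())))
            for m in planted
        ]
        assert model.mean_auc > max(singles)


class TestBuildSubtypeModels:
    def test_empty_target_list_gives_no_models(self, default_expr, default_annotations):
        assert build_subtype_models(default_expr, default_annotations, targets=[]) == []

    def test_degenerate_target_skipped_others_run(self):
        rng = np.random.default_rng(14)
        ann = two_group_annotations(30, 30)
        vals = rng.normal(0, 1.0, (6, 60))
        vals[1, :30] += 2.5
        expr = expr_matrix(vals)
        models = build_subtype_models(
            expr,
            ann,
            targets=[("ctnnb1", "mutated"), ("molecular", "MMRd")],  # ctnnb1 all unknown
            config=SfsConfig(n_repeats=3, n_selection_repeats=2, max_features=2, seed=0),
        )
        assert [m.contrast_name for m in models] == ["molecular=MMRd"]
        assert "m1" in models[0].selected_mirnas

    def test_planted_mmrd_panel_recovered(self):
        rng = np.random.default_rng(15)
        n_pos, n_neg = 48, 54
        vals = rng.normal(0, 1.0, (60, n_pos + n_neg))
        planted = [f"m{i}" for i in (5, 17, 29, 41, 53)]
        for m in planted:
            vals[int(m[1:]), :n_pos] += 1.0  # five independent 2x effects
        expr = expr_matrix(vals)
        ann = two_group_annotations(n_pos, n_neg)
        models = build_subtype_models(
            expr,
            ann,
            targets=[("molecular", "MMRd")],
            config=SfsConfig(n_repeats=5, n_selection_repeats=3, max_features=8, seed=1),
        )
        assert len(set(planted) & set(models[0].selected_mirnas)) >= 3
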