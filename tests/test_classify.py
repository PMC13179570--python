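"""Debris augmentation, penalized multinomial fit, calling, ADT thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import probcell as pc
from probcell.classify import TrainingSet, multinomial_objective, _softmax_scores


# ---------------------------------------------------------------------------
# debris thinning
# ---------------------------------------------------------------------------


class TestThinning:
    def test_factor_at_most_one_rejected(self):
        with pytest.raises(pc.ProbcellError, match="invalid factor"):
            pc.DebrisFactor(factor=1.0)

    def test_factor_near_one_retains_almost_everything(self):
        rng = np.random.default_rng(0)
        x = np.full(100, 50)
        thinned = pc.thin_counts(x, 1.0 + 1e-9, rng)
        assert thinned.sum() == x.sum()

    def test_total_mean_is_one_twentieth_over_replicates(self):
        # cell with total 4000 thinned at factor 20 -> mean total 200
        rng = np.random.default_rng(1)
        cell = np.full(40, 100)  # total 4000
        totals = [pc.thin_counts(cell, 20.0, rng).sum() for _ in range(1000)]
        assert abs(np.mean(totals) - 200.0) / 200.0 < 0.05

    def test_per_gene_expectation_matches_closed_form(self):
        rng = np.random.default_rng(2)
        gene_counts = np.array([0, 5, 40, 400, 2000])
        reps = np.array([pc.thin_counts(gene_counts, 20.0, rng) for _ in range(4000)])
        emp = reps.mean(axis=0)
        closed = gene_counts / 20.0
        nonzero = gene_counts > 0
        assert np.all(np.abs(emp[nonzero] - closed[nonzero]) / closed[nonzero] < 0.05)
        assert emp[0] == 0.0


class TestTrainingSetConstruction:
    def test_debris_rows_one_per_cell(self, small_ref, small_model):
        _, m, ann = small_ref
        ts = pc.make_debris_training(m, ann, pc.DebrisFactor(20.0, 0), panel_size=50)
        assert ts.features.shape[0] == 2 * len(ann)
        assert np.sum(ts.labels == "debris") == len(ann)
        assert set(ts.panel) <= set(m.gene_ids)
        # depth feature appended: panel + 1 columns
        assert ts.features.shape[1] == 51

    def test_no_annotations_rejected(self, small_ref):
        _, m, _ = small_ref
        with pytest.raises(pc.ProbcellError, match="empty reference"):
            pc.make_debris_training(m, [], pc.DebrisFactor(20.0, 0), panel_size=10)


# ---------------------------------------------------------------------------
# multinomial logistic regression
# ---------------------------------------------------------------------------


class TestTraining:
    def test_separable_two_class_problem_is_fit_exactly(self):
        rng = np.random.default_rng(3)
        a = rng.normal([0, 0], 0.3, size=(40, 2))
        b = rng.normal([5, 5], 0.3, size=(40, 2))
        ts = TrainingSet(
            features=np.vstack([a, b]),
            labels=np.array(["T"] * 40 + ["debris"] * 40),
            panel=["f1", "f2"], depth_feature_included=False,
        )
        model = pc.train_classifier(ts, lambda_reg=1e-4)
        P = _softmax_scores(model, ts.features)
        acc = np.mean(np.array(model.classes)[P.argmax(axis=1)] == ts.labels)
        assert acc == 1.0

    def test_gradient_matches_central_finite_differences(self):
        # 5-row instance, relative error < 1e-5
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3))
        Y = np.eye(3)[rng.integers(0, 3, size=5)]
        theta = rng.normal(scale=0.5, size=3 * 3 + 3)
        _, grad = multinomial_objective(theta, X, Y, lam=0.7)
        h = 1e-6
        fd = np.empty_like(theta)
        for i in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = (multinomial_objective(up, X, Y, 0.7)[0]
                     - multinomial_objective(dn, X, Y, 0.7)[0]) / (2 * h)
        assert np.max(np.abs(grad - fd)) / max(np.max(np.abs(fd)), 1.0) < 1e-5

    def test_class_with_zero_rows_rejected(self):
        ts = TrainingSet(features=np.zeros((3, 2)),
                         labels=np.array(["T", "T", "T"]),
                         panel=["a", "b"])
        with pytest.raises(pc.ProbcellError, match="degenerate class"):
            pc.train_classifier(ts)

    def test_nonfinite_features_rejected(self):
        ts = TrainingSet(features=np.array([[np.nan, 0], [0, 1], [1, 0]]),
                         labels=np.array(["T", "debris", "T"]), panel=["a", "b"])
        with pytest.raises(pc.ProbcellError, match="invalid feature"):
            pc.train_classifier(ts)

    def test_training_is_deterministic(self, small_ref):
        _, m, ann = small_ref
        ts = pc.make_debris_training(m, ann, pc.DebrisFactor(20.0, 0), panel_size=40)
        m1 = pc.train_classifier(ts, lambda_reg=0.5)
        m2 = pc.train_classifier(ts, lambda_reg=0.5)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        np.testing.assert_array_equal(m1.intercepts, m2.intercepts)

    def test_debris_is_last_class(self, small_model):
        assert small_model.classes[-1] == "debris"

    def test_agrees_with_reference_implementation(self):
        # independent cross-check against scikit-learn on a small instance
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 4))
        beta = rng.normal(size=(3, 4))
        y_idx = (X @ beta.T + rng.normal(scale=0.5, size=(120, 3))).argmax(axis=1)
        labels = np.array(["a", "b", "debris"])[y_idx]
        lam = 2.0
        ts = TrainingSet(X, labels, panel=list("wxyz"), depth_feature_included=False)
        ours = pc.train_classifier(ts, lambda_reg=lam)
        sk = LogisticRegression(C=1.0 / lam, tol=1e-10, max_iter=5000).fit(X, labels)
        P_ours = _softmax_scores(ours, X)
        order = [list(sk.classes_).index(c) for c in ours.classes]
        np.testing.assert_allclose(P_ours, sk.predict_proba(X)[:, order], atol=1e-4)

    def test_cv_regularization_selection_returns_grid_member(self, small_ref):
        _, m, ann = small_ref
        ts = pc.make_debris_training(m, ann[:120], pc.DebrisFactor(20.0, 0),
                                     panel_size=20)
        grid = [0.01, 1.0, 100.0]
        lam = pc.select_regularization(ts, grid=grid, folds=3, seed=0)
        assert lam in grid


# ---------------------------------------------------------------------------
# prediction and calling
# ---------------------------------------------------------------------------


class TestPrediction:
    def test_zero_model_gives_uniform_probabilities(self, tiny):
        model = pc.ClassifierModel(
            classes=["a", "b", "debris"],
            coefficients=np.zeros((3, 3)), intercepts=np.zeros(3),
            panel=["g0", "g1"], depth_feature_included=True,
        )
        raw = tiny([[3, 0], [0, 7]], genes=["g0", "g1"])
        res = pc.predict_proba(model, raw)
        for r in res:
            np.testing.assert_allclose(r.probabilities, 1 / 3, atol=1e-12)

    def test_probabilities_sum_to_one(self, small_model, small_ref):
        _, m, _ = small_ref
        res = pc.predict_proba(small_model, m)
        sums = np.array([r.probabilities.sum() for r in res])
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_all_zero_barcode_is_debris(self, small_model, tiny):
        raw = tiny(np.zeros((len(small_model.panel), 1), dtype=int),
                   genes=list(small_model.panel), barcodes=["empty"])
        res = pc.predict_proba(small_model, raw)
        assert res[0].called_label == "debris"

    def test_panel_mismatch_aborts(self, small_model, tiny):
        keep = small_model.panel[: len(small_model.panel) // 4]  # 75% missing
        raw = tiny(np.ones((len(keep), 2), dtype=int), genes=list(keep))
        with pytest.raises(pc.ProbcellError, match="panel mismatch"):
            pc.predict_proba(small_model, raw)

    def test_missing_panel_genes_zero_filled_with_warning(self, small_model,
                                                          small_ref, caplog):
        _, m, _ = small_ref
        drop = set(small_model.panel[:10])
        sub_genes = [g for g in m.gene_ids if g not in drop]
        rows = [m.gene_ids.index(g) for g in sub_genes]
        raw = pc.CountMatrix(sub_genes, m.barcode_ids, m.counts[rows, :])
        with caplog.at_level("WARNING", logger="probcell"):
            res = pc.predict_proba(small_model, raw)
        assert "zero-filling" in caplog.text
        assert len(res) == m.n_barcodes

    def test_barcode_order_permutation_equivariance(self, small_model, small_ref):
        _, m, _ = small_ref
        rng = np.random.default_rng(6)
        perm = rng.permutation(m.n_barcodes)
        shuffled = m.subset_barcodes([m.barcode_ids[i] for i in perm])
        res_a = {r.barcode_id: r.probabilities for r in pc.predict_proba(small_model, m)}
        res_b = {r.barcode_id: r.probabilities for r in pc.predict_proba(small_model, shuffled)}
        for b in m.barcode_ids:
            np.testing.assert_array_equal(res_a[b], res_b[b])


def _result(bc, probs, classes=("a", "b", "debris")):
    probs = np.asarray(probs, dtype=float)
    k = int(np.argmax(probs))
    return pc.ClassificationResult(bc, probs, list(classes)[k], float(probs[k]))


class TestCalling:
    def test_min_prob_zero_is_pure_argmax(self):
        calls = pc.call_cells([_result("b1", [0.4, 0.35, 0.25])], min_prob=0.0)
        assert calls["called_label"].tolist() == ["a"]

    def test_below_threshold_is_unassigned(self):
        calls = pc.call_cells([_result("b1", [0.4, 0.4, 0.2])], min_prob=0.5)
        assert calls["called_label"].tolist() == ["unassigned"]

    def test_exact_tie_goes_to_first_class_in_model_order(self):
        calls = pc.call_cells([_result("b1", [0.5, 0.5, 0.0])], min_prob=0.5)
        assert calls["called_label"].tolist() == ["a"]

    def test_accepted_cells_excludes_debris_and_unassigned(self):
        calls = pc.call_cells(
            [_result("b1", [0.9, 0.05, 0.05]), _result("b2", [0.05, 0.05, 0.9]),
             _result("b3", [0.4, 0.4, 0.2])])
        acc = pc.accepted_cells(calls)
        assert acc["barcode"].tolist() == ["b1"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
           st.floats(0.0, 1.0))
    def test_calls_respect_threshold_property(self, raw_scores, min_prob):
        probs = np.array(raw_scores) / np.sum(raw_scores)
        classes = [f"c{i}" for i in range(len(probs) - 1)] + ["debris"]
        calls = pc.call_cells([_result("b", probs, classes)], min_prob=min_prob)
        label = calls["called_label"][0]
        if probs.max() >= min_prob:
            assert label == classes[int(np.argmax(probs))]
        else:
            assert label == "unassigned"


class TestRecoveryReport:
    def test_all_above_cutoff_fold_is_one(self, tiny):
        raw = tiny(np.ones((600, 2), dtype=int))
        calls = pd.DataFrame({"barcode": ["b0", "b1"], "called_label": ["T", "T"],
                              "max_prob": [0.9, 0.9]})
        rep = pc.recovery_report(calls, raw, gene_cutoff=500)
        assert rep.loc["T", "fold_vs_cutoff"] == 1.0
        assert rep.loc["T", "n_below_cutoff"] == 0

    def test_shallow_type_recovered_beyond_fixed_cutoff(self, small_model, small_ref):
        cfg, _, _ = small_ref
        eval_cfg = pc.default_reference_config(seed=23, n_cells_per_type=100,
                                               n_genes=cfg.n_genes)
        raw, ann = pc.simulate_reference(eval_cfg)
        calls = pc.call_cells(pc.predict_proba(small_model, raw))
        rep = pc.recovery_report(calls, raw, gene_cutoff=500)
        assert rep.loc["neutrophil", "fold_vs_cutoff"] > 1.0

    def test_unknown_barcodes_rejected_and_cutoff_validated(self, tiny):
        raw = tiny([[1]])
        calls = pd.DataFrame({"barcode": ["zzz"], "called_label": ["T"],
                              "max_prob": [0.9]})
        with pytest.raises(pc.ProbcellError, match="unknown barcodes"):
            pc.recovery_report(calls, raw)
        with pytest.raises(pc.ProbcellError, match="invalid cutoff"):
            pc.recovery_report(pd.DataFrame({"barcode": ["b0"], "called_label": ["T"],
                                             "max_prob": [0.9]}), raw, gene_cutoff=-1)

    def test_no_cell_above_cutoff_reports_infinite_fold(self, tiny):
        raw = tiny(np.eye(600, 1, dtype=int))  # barcode with 1 detected gene
        calls = pd.DataFrame({"barcode": ["b0"], "called_label": ["T"],
                              "max_prob": [0.9]})
        rep = pc.recovery_report(calls, raw, gene_cutoff=500)
        assert np.isinf(rep.loc["T", "fold_vs_cutoff"])

    def test_expected_type_without_calls_reports_not_applicable(self, tiny):
        raw = tiny(np.ones((600, 1), dtype=int))
        calls = pd.DataFrame({"barcode": ["b0"], "called_label": ["T"],
                              "max_prob": [0.9]})
        rep = pc.recovery_report(calls, raw, expected_types=["T", "absent"])
        assert rep.loc["absent", "n_cells"] == 0
        assert np.isnan(rep.loc["absent", "fold_vs_cutoff"])


class TestDepthFeature:
    def test_depth_feature_improves_debris_separation(self, small_ref):
        # the design premise: coverage carries competing-class signal
        cfg, m, ann = small_ref
        eval_cfg = pc.default_reference_config(seed=29, n_cells_per_type=150,
                                               n_genes=cfg.n_genes)
        eval_cfg.n_debris = 300
        mix, ann2 = pc.simulate_reference(eval_cfg)
        raw = pc.combine_matrices(mix, pc.simulate_debris(eval_cfg))
        truth = {a.barcode_id: a.cell_type for a in ann2}

        def debris_error(depth_feature):
            ts = pc.make_debris_training(m, ann, pc.DebrisFactor(20.0, 0),
                                         panel_size=100, depth_feature=depth_feature)
            model = pc.train_classifier(ts, lambda_reg=1.0)
            calls = pc.call_cells(pc.predict_proba(model, raw))
            acc = pc.accepted_cells(calls)
            accepted = set(acc["barcode"])
            false_accept = sum(1 for b in raw.barcode_ids
                               if b not in truth and b in accepted)
            missed_neut = sum(1 for b, t in truth.items()
                              if t == "neutrophil" and b not in accepted)
            return false_accept + missed_neut

        assert debris_error(True) <= debris_error(False)


class TestAdtThreshold:
    @staticmethod
    def _bimodal(n=2000, seed=0, mu=(3.0, 6.0)):
        rng = np.random.default_rng(seed)
        logs = np.concatenate([rng.normal(mu[0], 0.3, n // 2),
                               rng.normal(mu[1], 0.4, n - n // 2)])
        return np.round(np.expm1(logs)).astype(int)

    def test_threshold_between_sample_modes(self):
        counts = self._bimodal()
        res = pc.adt_threshold(counts)
        assert res.valid
        assert res.modes[0] < res.threshold < res.modes[1]
        # threshold separates the two generative components
        assert 3.0 + 3 * 0.3 < res.threshold < 6.0 - 3 * 0.4 + 1.0

    def test_unimodal_sample_invalid(self):
        rng = np.random.default_rng(1)
        counts = np.round(np.expm1(rng.normal(4.0, 0.3, 2000))).astype(int)
        assert not pc.adt_threshold(counts).valid

    def test_identical_counts_degenerate(self):
        res = pc.adt_threshold(np.full(100, 7))
        assert not res.valid and res.reason == "degenerate"

    def test_scaling_counts_by_e_shifts_threshold_by_one(self):
        counts = self._bimodal(seed=2)
        t1 = pc.adt_threshold(counts).threshold
        t2 = pc.adt_threshold(np.round(counts * np.e).astype(int)).threshold
        assert abs((t2 - t1) - 1.0) < 0.35

    def test_too_few_observations_rejected(self):
        with pytest.raises(pc.ProbcellError, match="50 observations"):
            pc.adt_threshold(np.arange(10))


class TestModelSerialization:
    def test_round_trip(self, small_model, tmp_path, small_ref):
        path = str(tmp_path / "model.json")
        pc.save_model(small_model, path)
        back = pc.load_model(path)
        np.testing.assert_array_equal(back.coefficients, small_model.coefficients)
        assert back.classes == small_model.classes
        assert back.panel == small_model.panel
        _, m, _ = small_ref
        p1 = np.array([r.probabilities for r in pc.predict_proba(small_model, m)])
        p2 = np.array([r.probabilities for r in pc.predict_proba(back, m)])
        np.testing.assert_array_equal(p1, p2)
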