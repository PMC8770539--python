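import numpy as np
import pandas as pd
import pytest

import epiorigin as eo
from epiorigin.classifier import (
    OriginModel,
    evaluate,
    predict_origin,
    split_cohort,
    train_ovr_forest,
    undersample_balance,
)
from epiorigin.omics_io import ValidationError

from conftest import make_beta, make_samples


class TestSplit:
    def _sheet(self, n, classes=None, paired=False):
        classes = classes or ["A"] * n
        pairs = [f"p{i}" for i in range(n)] if paired else [""] * n
        conds = ["tumor"] * n
        if paired:
            classes = classes + classes
            conds = conds + ["normal"] * n
            pairs = pairs + [f"p{i}" for i in range(n)]
        ids = [f"s{i:03d}" for i in range(len(conds))]
        return eo.SampleSheet(pd.DataFrame({
            "class_label": classes, "condition": conds,
            "pair_id": pairs, "cohort": ""}, index=pd.Index(ids, name="sample_id")))

    def test_seventy_thirty(self):
        out = split_cohort(self._sheet(100), seed=0).table
        assert (out["cohort"] == "train").sum() == 70
        assert (out["cohort"] == "test").sum() == 30

    def test_rounding_toward_training(self):
        out = split_cohort(self._sheet(11), seed=0).table
        assert (out["cohort"] == "train").sum() == 8
        assert (out["cohort"] == "test").sum() == 3

    def test_deterministic_and_stratified(self):
        sheet = self._sheet(40, classes=["A"] * 20 + ["B"] * 20)
        a = split_cohort(sheet, seed=5).table["cohort"]
        b = split_cohort(sheet, seed=5).table["cohort"]
        assert (a == b).all()
        t = split_cohort(sheet, seed=5).table
        for cl in ("A", "B"):
            sub = t[t["class_label"] == cl]
            assert (sub["cohort"] == "train").sum() == 14

    def test_pairs_never_split(self):
        out = split_cohort(self._sheet(20, paired=True), seed=1).table
        for pid, grp in out.groupby("pair_id"):
            assert grp["cohort"].nunique() == 1

    def test_small_class_errors(self):
        with pytest.raises(ValidationError, match="need >= 4"):
            split_cohort(self._sheet(3), seed=0)


class TestUndersample:
    def _labels(self, spec):
        vals, idx = [], []
        for cl, n in spec.items():
            vals += [cl] * n
            idx += [f"{cl}{i:03d}" for i in range(n)]
        return pd.Series(vals, index=idx)

    def test_even_allocation_over_rest_classes(self):
        labels = self._labels({"pos": 30, **{f"r{i}": 30 for i in range(10)}})
        idx, warn = undersample_balance(labels, "pos", seed=0)
        assert warn == []
        chosen = labels.loc[idx]
        assert (chosen == "pos").sum() == 30
        rest = chosen[chosen != "pos"].value_counts()
        assert rest.sum() == 30 and set(rest) == {3}

    def test_small_rest_pool_keeps_all_with_warning(self):
        labels = self._labels({"pos": 10, "r0": 4, "r1": 3})
        idx, warn = undersample_balance(labels, "pos", seed=0)
        assert len(idx) == 17 and warn

    def test_deterministic(self):
        labels = self._labels({"pos": 9, "r0": 20, "r1": 20})
        a, _ = undersample_balance(labels, "pos", seed=3)
        b, _ = undersample_balance(labels, "pos", seed=3)
        assert a == b
        chosen = labels.loc[a]
        assert (chosen != "pos").sum() == 9  # balance contract

    def test_uneven_pools_redistribute(self):
        labels = self._labels({"pos": 20, "r0": 5, "r1": 40})
        idx, _ = undersample_balance(labels, "pos", seed=0)
        chosen = labels.loc[idx]
        assert (chosen != "pos").sum() == 20


def _separable_cohort(seed=0, n_per_class=30, n_classes=3, noise=0.02):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    classes = [f"c{i // n_per_class}" for i in range(n)]
    rows = []
    for k in range(n_classes):
        row = np.where(np.char.equal(classes, f"c{k}"), 0.85, 0.15)
        rows.append(np.clip(row + noise * rng.standard_normal(n), 0, 1))
    beta = make_beta(np.vstack(rows), probes=[f"cgM{k}" for k in range(n_classes)])
    sheet = make_samples(["tumor"] * n, classes=classes)
    return split_cohort(sheet, seed=seed), beta


class TestTrainEvaluate:
    def test_separable_fixture_is_learned(self):
        samples, beta = _separable_cohort()
        model = train_ovr_forest(beta, samples, list(beta.probe_ids), seed=0)
        for cl, hp in model.hyperparams.items():
            assert 10 <= hp["n_trees"] <= 100
            assert hp["criterion"] in ("gini", "entropy")
        report = evaluate(model, beta, samples, cohort="test", n_boot=50, seed=0)
        assert report.overall_accuracy >= 0.95
        assert (report.per_class["auc"] >= 0.95).all()
        assert report.confusion.sum(axis=1).tolist() == report.per_class["n"].tolist()

    def test_probabilities_renormalized_and_deterministic(self):
        samples, beta = _separable_cohort(seed=2)
        model = train_ovr_forest(beta, samples, list(beta.probe_ids), seed=2)
        pred = predict_origin(model, beta)
        probs = pred[model.classes].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        pred2 = predict_origin(model, beta)
        pd.testing.assert_frame_equal(pred, pred2)

    def test_missing_panel_probe_is_an_error_naming_it(self):
        samples, beta = _separable_cohort(seed=3)
        model = train_ovr_forest(beta, samples, list(beta.probe_ids), seed=3)
        reduced = eo.BetaMatrix(beta.values.drop(index=["cgM1"]))
        with pytest.raises(ValidationError, match="cgM1"):
            predict_origin(model, reduced)

    def test_shuffled_labels_auc_is_chance(self):
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            samples, beta = _separable_cohort(seed=seed, n_per_class=40, n_classes=2)
            t = samples.table.copy()
            t["class_label"] = rng.permutation(t["class_label"].to_numpy())
            shuffled = eo.SampleSheet(t)
            model = train_ovr_forest(beta, shuffled, list(beta.probe_ids),
                                     seed=seed, tree_grid=(25,))
            rep = evaluate(model, beta, shuffled, cohort="test", n_boot=10, seed=seed)
            aucs.append(rep.per_class["auc"].mean())
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_model_round_trips_bit_exactly(self, tmp_path):
        samples, beta = _separable_cohort(seed=4)
        model = train_ovr_forest(beta, samples, list(beta.probe_ids), seed=4)
        p1, p2 = tmp_path / "m1.pkl", tmp_path / "m2.pkl"
        model.save(p1)
        model.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = OriginModel.load(p1)
        pd.testing.assert_frame_equal(predict_origin(back, beta),
                                      predict_origin(model, beta))

    def test_metastatic_style_samples_trace_back_to_origin(self):
        samples, beta = _separable_cohort(seed=5)
        model = train_ovr_forest(beta, samples, list(beta.probe_ids), seed=5)
        rng = np.random.default_rng(5)
        n_new = 60
        sig = np.vstack([np.r_[np.full(1, 0.85), np.full(2, 0.15)]
                         for _ in range(n_new)]).T  # class c0 signature
        noisy = np.clip(sig + rng.normal(0, 0.05, sig.shape), 0, 1)
        new = make_beta(noisy, probes=list(beta.probe_ids),
                        samples=[f"met{i:02d}" for i in range(n_new)])
        pred = predict_origin(model, new)
        assert (pred["predicted_class"] == "c0").mean() >= 0.95
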