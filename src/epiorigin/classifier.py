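"""Tissue-of-origin classification from a small CpG marker panel.

One binary random forest per class (one vs rest), each trained on an
under-sampled balanced subset of the training cohort; hyperparameters
(number of trees in 10-100, split criterion gini/entropy) are chosen by
out-of-bag score, ties resolved toward fewer trees and gini.  Multi-class
prediction renormalizes the per-class positive probabilities to sum to one
and takes the argmax (ties toward the class with larger training
prevalence, then lexicographic).  Evaluation reports per-class one-vs-rest
AUC (rank statistic), argmax accuracy and a confusion matrix, with 95%
confidence intervals from cross-validation folds (training) or stratified
bootstrap resampling (held-out cohorts).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .omics_io import BetaMatrix, SampleSheet, ValidationError

DEFAULT_TREE_GRID = (10, 25, 50, 100)  # within the 10-100 search range
CRITERIA = ("gini", "entropy")
TRAIN_RATIO = 0.7
MODEL_FORMAT_VERSION = 1


def split_cohort(samples: SampleSheet, ratio: float = TRAIN_RATIO, seed: int = 0) -> SampleSheet:
    """Stratified train/test split of tumor samples (rounding toward train).

    Matched normal samples always follow their tumor pair so pairs are never
    split across cohorts; unpaired normals go to training.
    """
    if not (0 < ratio < 1):
        raise ValidationError("ratio must lie in (0,1)")
    t = samples.table.copy()
    rng = np.random.default_rng(seed)
    tumor = t[t["condition"] == "tumor"]
    cohort = pd.Series("", index=t.index, dtype=object)
    for cl, grp in tumor.groupby("class_label", sort=True):
        ids = np.array(sorted(grp.index))
        if len(ids) < 4:
            raise ValidationError(f"class {cl!r} has {len(ids)} tumor samples; need >= 4 to split")
        rng.shuffle(ids)
        n_train = int(np.ceil(ratio * len(ids)))
        cohort[ids[:n_train]] = "train"
        cohort[ids[n_train:]] = "test"
    pair_cohort = {t.loc[s, "pair_id"]: c for s, c in cohort.items()
                   if c and t.loc[s, "pair_id"]}
    for s in t.index[t["condition"] == "normal"]:
        pid = t.loc[s, "pair_id"]
        cohort[s] = pair_cohort.get(pid, "train") if pid else "train"
    out = t.assign(cohort=cohort)
    return SampleSheet(out)


def undersample_balance(labels: pd.Series, positive_class: str, seed: int = 0
                        ) -> tuple[list, list[str]]:
    """Balanced one-vs-rest index set: all positives plus an even draw of rest.

    Rest samples are drawn without replacement, allocated as evenly as
    possible across the rest classes (remainder classes chosen by a seeded
    draw).  If the rest pool is smaller than the positive count, everything
    is kept and a warning is returned.
    """
    rng = np.random.default_rng(seed)
    pos = sorted(labels.index[labels == positive_class])
    if not pos:
        raise ValidationError(f"positive class {positive_class!r} has no samples")
    rest = labels[labels != positive_class]
    warnings: list[str] = []
    if len(rest) <= len(pos):
        if len(rest) < len(pos):
            warnings.append(
                f"rest pool ({len(rest)}) smaller than positives ({len(pos)}); keeping all"
            )
        return pos + sorted(rest.index), warnings

    rest_classes = sorted(rest.unique())
    quota = {c: len(pos) // len(rest_classes) for c in rest_classes}
    extra = rng.choice(rest_classes, size=len(pos) % len(rest_classes), replace=False)
    for c in extra:
        quota[c] += 1
    chosen: list = []
    short = 0
    for c in rest_classes:
        pool = sorted(rest.index[rest == c])
        take = min(quota[c], len(pool))
        short += quota[c] - take
        idx = rng.choice(len(pool), size=take, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    if short:  # redistribute shortfall over classes with spare samples
        leftovers = sorted(set(rest.index) - set(chosen))
        idx = rng.choice(len(leftovers), size=min(short, len(leftovers)), replace=False)
        chosen.extend(leftovers[i] for i in sorted(idx))
    return pos + chosen, warnings


def _make_estimator(algorithm: str, n_trees: int, criterion: str, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=n_trees, criterion=criterion, oob_score=True,
            bootstrap=True, random_state=seed, n_jobs=1,
        )
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed)
    if algorithm == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValidationError(f"unknown algorithm {algorithm!r}")


@dataclass
class OriginModel:
    panel: list[str]
    classes: list[str]
    forests: dict[str, object]
    hyperparams: dict[str, dict]
    prevalence: dict[str, int]  # training positives per class
    seed: int
    algorithm: str = "rf"
    cv_metrics: pd.DataFrame | None = None
    version: int = MODEL_FORMAT_VERSION
    warnings: list[str] = field(default_factory=list)

    def save(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)
        return path

    @classmethod
    def load(cls, path: Path) -> "OriginModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls) or model.version != MODEL_FORMAT_VERSION:
            raise ValidationError(f"unsupported model file {path}")
        return model


def _panel_matrix(model_panel: list[str], beta: BetaMatrix, sample_ids: list[str]) -> np.ndarray:
    missing = [p for p in model_panel if p not in set(beta.probe_ids)]
    if missing:
        raise ValidationError(f"panel probes missing from beta matrix: {missing}")
    x = beta.values.loc[model_panel, sample_ids].to_numpy().T
    if np.isnan(x).any():
        raise ValidationError("beta matrix contains missing values for panel probes")
    return x


def train_ovr_forest(
    beta: BetaMatrix,
    samples: SampleSheet,
    panel: list[str],
    seed: int = 0,
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    algorithm: str = "rf",
    n_cv_folds: int = 10,
) -> OriginModel:
    """Train one balanced binary classifier per class on the training cohort."""
    if any(n < 10 or n > 100 for n in tree_grid):
        raise ValidationError("tree grid must stay within 10-100")
    train_ids = [s for s in samples.tumor_samples("train") if s in set(beta.sample_ids)]
    if not train_ids:
        raise ValidationError("no training-cohort tumor samples (run split_cohort first)")
    labels = samples.table.loc[train_ids, "class_label"]
    classes = sorted(labels.unique())
    x_all = _panel_matrix(panel, beta, train_ids)
    pos_of = {s: i for i, s in enumerate(train_ids)}

    forests, hyper, prevalence = {}, {}, {}
    cv_rows = []
    all_warnings: list[str] = []
    for ci, cl in enumerate(classes):
        idx, warn = undersample_balance(labels, cl, seed=seed + ci)
        all_warnings.extend(warn)
        rows = [pos_of[s] for s in idx]
        x = x_all[rows]
        y = (labels.loc[idx] == cl).to_numpy().astype(int)
        if algorithm == "rf":
            best = None
            for n_trees in sorted(tree_grid):
                for criterion in CRITERIA:
                    est = _make_estimator("rf", n_trees, criterion, seed)
                    with warnings.catch_warnings():
                        # small forests can miss OOB coverage for a few samples
                        warnings.simplefilter("ignore", UserWarning)
                        est.fit(x, y)
                    cand = (est.oob_score_, -n_trees, criterion == "gini", est)
                    # ties resolve toward fewer trees, then gini
                    if best is None or cand[:3] > best[:3]:
                        best = cand
            forests[cl] = best[3]
            hyper[cl] = {"n_trees": -best[1], "criterion": "gini" if best[2] else "entropy",
                         "oob_score": float(best[0])}
        else:
            est = _make_estimator(algorithm, 0, "gini", seed)
            est.fit(x, y)
            forests[cl] = est
            hyper[cl] = {"algorithm": algorithm}
        prevalence[cl] = int((labels == cl).sum())

        folds = min(n_cv_folds, int(np.bincount(y).min()))
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            fold_acc, fold_auc = [], []
            for tr, te in cv.split(x, y):
                est = _make_estimator(algorithm, hyper[cl].get("n_trees", 50),
                                      hyper[cl].get("criterion", "gini"), seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    est.fit(x[tr], y[tr])
                prob = est.predict_proba(x[te])[:, list(est.classes_).index(1)]
                fold_acc.append(float((est.predict(x[te]) == y[te]).mean()))
                if len(np.unique(y[te])) == 2:
                    fold_auc.append(float(roc_auc_score(y[te], prob)))
            cv_rows.append({
                "class_label": cl, "folds": folds,
                "cv_accuracy": float(np.mean(fold_acc)),
                "cv_accuracy_se": float(np.std(fold_acc, ddof=1) / np.sqrt(len(fold_acc))),
                "cv_auc": float(np.mean(fold_auc)) if fold_auc else np.nan,
                "cv_auc_se": float(np.std(fold_auc, ddof=1) / np.sqrt(len(fold_auc)))
                if len(fold_auc) > 1 else np.nan,
            })
    return OriginModel(
        panel=list(panel), classes=classes, forests=forests, hyperparams=hyper,
        prevalence=prevalence, seed=seed, algorithm=algorithm,
        cv_metrics=pd.DataFrame(cv_rows), warnings=all_warnings,
    )


def predict_origin(model: OriginModel, beta: BetaMatrix,
                   sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample renormalized class probabilities and argmax label."""
    ids = list(sample_ids) if sample_ids is not None else list(beta.sample_ids)
    x = _panel_matrix(model.panel, beta, ids)
    raw = np.column_stack([
        model.forests[cl].predict_proba(x)[:, list(model.forests[cl].classes_).index(1)]
        for cl in model.classes
    ])
    total = raw.sum(axis=1, keepdims=True)
    probs = np.where(total > 0, raw / np.where(total > 0, total, 1.0),
                     1.0 / len(model.classes))
    # argmax with ties toward larger training prevalence, then lexicographic
    order = sorted(range(len(model.classes)),
                   key=lambda i: (-model.prevalence[model.classes[i]], model.classes[i]))
    ordered = probs[:, order]
    pick = np.argmax(ordered, axis=1)
    labels = [model.classes[order[i]] for i in pick]
    out = pd.DataFrame(probs, index=ids, columns=model.classes)
    out["predicted_class"] = labels
    out.index.name = "sample_id"
    return out


@dataclass
class ClassifierReport:
    overall_accuracy: float
    overall_accuracy_ci: tuple[float, float]
    per_class: pd.DataFrame  # class_label, n, accuracy, auc + CIs
    confusion: pd.DataFrame  # rows true class, columns predicted
    cv_metrics: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "overall_accuracy_ci": list(self.overall_accuracy_ci),
            "per_class": self.per_class.to_dict(orient="records"),
            "confusion": self.confusion.to_dict(),
            "cv_metrics": self.cv_metrics.to_dict(orient="records")
            if self.cv_metrics is not None else None,
            "warnings": self.warnings,
        }


def evaluate(
    model: OriginModel,
    beta: BetaMatrix,
    samples: SampleSheet,
    cohort: str = "test",
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassifierReport:
    """Held-out evaluation with stratified-bootstrap confidence intervals."""
    ids = [s for s in samples.tumor_samples(cohort) if s in set(beta.sample_ids)]
    if not ids:
        raise ValidationError(f"no tumor samples in cohort {cohort!r}")
    truth = samples.table.loc[ids, "class_label"]
    warnings = []
    extra = sorted(set(truth.unique()) - set(model.classes))
    if extra:
        warnings.append(f"classes absent from the model skipped: {extra}")
        ids = [s for s in ids if truth[s] in set(model.classes)]
        truth = truth.loc[ids]
    pred = predict_origin(model, beta, ids)
    y_true = truth.to_numpy()
    y_pred = pred["predicted_class"].to_numpy()
    probs = pred[model.classes].to_numpy()

    overall = float((y_true == y_pred).mean())
    rng = np.random.default_rng(seed)
    class_rows = {cl: np.flatnonzero(y_true == cl) for cl in model.classes}

    def stratified_resample() -> np.ndarray:
        parts = [rows[rng.integers(0, len(rows), len(rows))]
                 for rows in class_rows.values() if len(rows)]
        return np.concatenate(parts)

    acc_boot, auc_boot = [], {cl: [] for cl in model.classes}
    for _ in range(n_boot):
        take = stratified_resample()
        acc_boot.append((y_true[take] == y_pred[take]).mean())
        for ci, cl in enumerate(model.classes):
            yb = (y_true[take] == cl).astype(int)
            if 0 < yb.sum() < len(yb):
                auc_boot[cl].append(roc_auc_score(yb, probs[take, ci]))

    def ci(values, point):
        if len(values) < 2:
            return (point, point)
        se = float(np.std(values, ddof=1))
        return (max(0.0, point - 1.96 * se), min(1.0, point + 1.96 * se))

    rows = []
    for ci_idx, cl in enumerate(model.classes):
        mask = y_true == cl
        n_cl = int(mask.sum())
        acc_cl = float(((y_pred == cl) == mask).mean())  # one-vs-rest accuracy
        ybin = mask.astype(int)
        auc_cl = float(roc_auc_score(ybin, probs[:, ci_idx])) if 0 < n_cl < len(ids) else np.nan
        lo, hi = ci(auc_boot[cl], auc_cl) if not np.isnan(auc_cl) else (np.nan, np.nan)
        rows.append({"class_label": cl, "n": n_cl, "accuracy": acc_cl,
                     "auc": auc_cl, "auc_ci_low": lo, "auc_ci_high": hi})
    per_class = pd.DataFrame(rows)
    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=model.classes),
        index=model.classes, columns=model.classes,
    )
    return ClassifierReport(
        overall_accuracy=overall,
        overall_accuracy_ci=ci(acc_boot, overall),
        per_class=per_class,
        confusion=conf,
        cv_metrics=model.cv_metrics,
        warnings=warnings,
    )
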