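"""Two-stage tissue-specific CpG marker selection.

Stage 1 (statistical filter): for every candidate probe and every class, a
Welch t-test of the class's tumor samples against all other tumor samples
(one vs rest), BH-adjusted across probes within the class; a probe passes
for a class when q < 0.05 and the standard deviation of its beta value over
*all* tumor samples exceeds 0.2 (pooled SD: genuinely tissue-specific probes
are spread out across classes even when tight within each class).

Stage 2 (model-based ranking): a multiclass gradient-boosted tree ensemble
is fit on the passing probes and each probe is ranked by the mean absolute
Shapley attribution over samples and classes (exact tree-path attribution).
The panel size is chosen where the 10-fold cross-validated accuracy of a
random forest on the top-k probes reaches a plateau: the smallest k whose
next ``patience`` increments each improve accuracy by less than ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .differential import bh_adjust
from .omics_io import BetaMatrix, SampleSheet, ValidationError

OVR_Q_GATE = 0.05
OVR_SD_GATE = 0.2
MIN_CLASS_SAMPLES = 3


@dataclass
class BoosterConfig:
    """Gradient-boosting settings for the Shapley ranking (deterministic)."""

    n_rounds: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    colsample_bytree: float = 0.8  # lets exactly collinear probes share credit

    def params(self, n_classes: int, seed: int) -> dict:
        return {
            "objective": "multi:softprob",
            "num_class": n_classes,
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "colsample_bytree": self.colsample_bytree,
            "seed": seed,
            "nthread": 1,
            "verbosity": 0,
        }


def ovr_specific_filter(
    beta: BetaMatrix,
    samples: SampleSheet,
    candidate_probes: list[str] | None = None,
    adjust: str = "bh",
) -> pd.DataFrame:
    """One-vs-rest Welch t-test + pooled-SD gate per (probe, class).

    ``adjust`` is "bh" (default) or "bonferroni".  Classes with fewer than 3
    tumor samples are skipped (recorded in the frame's attrs warnings).
    """
    tumor = [s for s in samples.tumor_samples() if s in set(beta.sample_ids)]
    labels = samples.table.loc[tumor, "class_label"]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes among tumor samples")
    if candidate_probes is None:
        candidate_probes = list(beta.probe_ids)
    if not candidate_probes:
        raise ValidationError("candidate probe list is empty")
    mat = beta.values.loc[candidate_probes, tumor]
    if mat.isna().any().any():
        raise ValidationError("beta matrix contains missing values; impute first")
    arr = mat.to_numpy()
    pooled_sd = arr.std(axis=1, ddof=1)

    warnings: list[str] = []
    frames = []
    for cl in classes:
        in_cl = (labels == cl).to_numpy()
        if in_cl.sum() < MIN_CLASS_SAMPLES:
            warnings.append(f"class {cl!r} skipped: only {int(in_cl.sum())} tumor samples")
            continue
        res = stats.ttest_ind(arr[:, in_cl], arr[:, ~in_cl], axis=1, equal_var=False)
        p = np.nan_to_num(res.pvalue, nan=1.0)
        if adjust == "bonferroni":
            q = np.minimum(p * len(p), 1.0)
        else:
            q = bh_adjust(p)
        frames.append(pd.DataFrame({
            "probe_id": candidate_probes,
            "class_label": cl,
            "ovr_q": q,
            "sd": pooled_sd,
            "passes": (q < OVR_Q_GATE) & (pooled_sd > OVR_SD_GATE),
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["probe_id", "class_label", "ovr_q", "sd", "passes"])
    out.attrs["warnings"] = warnings
    return out


def shapley_rank(
    beta: BetaMatrix,
    samples: SampleSheet,
    probes: list[str],
    seed: int = 0,
    booster: BoosterConfig | None = None,
    cohort: str | None = "train",
) -> pd.DataFrame:
    """Rank probes by mean |Shapley attribution| of a multiclass booster.

    Attributions are exact tree-path (TreeSHAP) contributions from the
    fitted gradient-boosted ensemble, averaged over samples and classes;
    ties are broken by probe id.
    """
    booster = booster or BoosterConfig()
    if not probes:
        raise ValidationError("no probes to rank")
    tumor = [s for s in samples.tumor_samples(cohort) if s in set(beta.sample_ids)]
    if not tumor:  # fall back to all tumor samples when no cohort was assigned
        tumor = [s for s in samples.tumor_samples() if s in set(beta.sample_ids)]
    labels = pd.Categorical(samples.table.loc[tumor, "class_label"])
    if len(labels.categories) < 2:
        raise ValidationError("need >= 2 classes to rank markers")
    x = beta.values.loc[probes, tumor].to_numpy().T
    dtrain = xgb.DMatrix(x, label=labels.codes, feature_names=list(probes))
    model = xgb.train(booster.params(len(labels.categories), seed), dtrain,
                      num_boost_round=booster.n_rounds)
    contrib = model.predict(dtrain, pred_contribs=True)
    # multiclass: (n_samples, n_classes, n_features + 1); last column is bias
    contrib = np.asarray(contrib)
    if contrib.ndim == 2:
        contrib = contrib[:, None, :]
    importance = np.abs(contrib[:, :, :-1]).mean(axis=(0, 1))
    out = pd.DataFrame({"probe_id": probes, "importance": importance})
    return out.sort_values(["importance", "probe_id"], ascending=[False, True]).reset_index(drop=True)


def cumulative_cv_accuracy(
    beta: BetaMatrix,
    samples: SampleSheet,
    ranked_probes: list[str],
    seed: int = 0,
    max_k: int | None = None,
    n_trees: int = 50,
    n_folds: int = 10,
    cohort: str | None = "train",
) -> list[float]:
    """10-fold CV accuracy of a random forest on the top-k probes, k=1..K."""
    tumor = [s for s in samples.tumor_samples(cohort) if s in set(beta.sample_ids)]
    if not tumor:
        tumor = [s for s in samples.tumor_samples() if s in set(beta.sample_ids)]
    labels = pd.Categorical(samples.table.loc[tumor, "class_label"]).codes
    k_max = min(len(ranked_probes), max_k) if max_k else len(ranked_probes)
    accs = []
    x_full = beta.values.loc[ranked_probes[:k_max], tumor].to_numpy().T
    folds = min(n_folds, int(np.bincount(labels).min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    for k in range(1, k_max + 1):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        accs.append(float(cross_val_score(clf, x_full[:, :k], labels, cv=cv,
                                          scoring="accuracy").mean()))
    return accs


def select_plateau_k(cumulative_accuracy: list[float], epsilon: float = 0.005,
                     patience: int = 2) -> int:
    """Smallest k whose next ``patience`` increments each gain < epsilon.

    Near the end of the sequence fewer than ``patience`` increments may
    remain; the rule then uses all that are available (at least one).  If it
    never fires, the full length K is returned.
    """
    if not len(cumulative_accuracy):
        raise ValidationError("cumulative accuracy sequence is empty")
    if epsilon <= 0 or patience < 1:
        raise ValidationError("epsilon must be > 0 and patience >= 1")
    acc = list(cumulative_accuracy)
    n = len(acc)
    for k in range(1, n + 1):
        future = [acc[j] - acc[j - 1] for j in range(k, min(k + patience, n))]
        if future and all(d < epsilon for d in future):
            return k
    return n


@dataclass
class MarkerRanking:
    ranking: pd.DataFrame  # probe_id, importance (non-increasing)
    cumulative_accuracy: list[float]
    selected_k: int
    panel: list[str] = field(default_factory=list)


def select_markers(
    beta: BetaMatrix,
    samples: SampleSheet,
    candidate_probes: list[str] | None = None,
    epsilon: float = 0.005,
    patience: int = 2,
    seed: int = 0,
    max_k: int | None = 12,
    booster: BoosterConfig | None = None,
    cohort: str | None = "train",
) -> tuple[pd.DataFrame, MarkerRanking]:
    """Full marker stage: OVR filter -> Shapley ranking -> plateau panel."""
    candidates = ovr_specific_filter(beta, samples, candidate_probes)
    passing = sorted(candidates.loc[candidates["passes"], "probe_id"].unique())
    if not passing:
        raise ValidationError("no probes pass the one-vs-rest filter")
    ranking = shapley_rank(beta, samples, passing, seed=seed, booster=booster, cohort=cohort)
    ranked = list(ranking["probe_id"])
    accs = cumulative_cv_accuracy(beta, samples, ranked, seed=seed, max_k=max_k, cohort=cohort)
    k = select_plateau_k(accs, epsilon=epsilon, patience=patience)
    return candidates, MarkerRanking(ranking, accs, k, ranked[:k])
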