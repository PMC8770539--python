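import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epiorigin as eo
from epiorigin.marker_selection import (
    cumulative_cv_accuracy,
    ovr_specific_filter,
    select_markers,
    select_plateau_k,
    shapley_rank,
)
from epiorigin.omics_io import ValidationError

from conftest import make_beta, make_samples


def _cohort(n_per_class, n_classes=3):
    n = n_per_class * n_classes
    classes = [f"c{i // n_per_class}" for i in range(n)]
    return make_samples(["tumor"] * n, classes=classes)


class TestOvrFilter:
    def test_strong_class_marker_passes(self):
        rng = np.random.default_rng(0)
        n = 20
        row = np.r_[0.9 + 0.02 * rng.standard_normal(n),
                    0.1 + 0.02 * rng.standard_normal(np.int64(2 * n))]
        out = ovr_specific_filter(make_beta(np.clip(row, 0, 1)[None, :]), _cohort(n))
        rec = out.set_index("class_label")
        assert bool(rec.loc["c0", "passes"])
        assert rec.loc["c0", "sd"] > 0.2  # pooled spread from the class gap

    def test_uniform_probe_fails_both_gates(self):
        rng = np.random.default_rng(1)
        row = 0.5 + 0.03 * rng.standard_normal(60)
        out = ovr_specific_filter(make_beta(np.clip(row, 0, 1)[None, :]), _cohort(20))
        assert not out["passes"].any()
        assert (out["sd"] < 0.2).all()

    def test_sd_gate_blocks_small_gap_despite_significance(self):
        rng = np.random.default_rng(2)
        n = 40
        row = np.r_[0.55 + 0.01 * rng.standard_normal(n),
                    0.45 + 0.01 * rng.standard_normal(np.int64(2 * n))]
        out = ovr_specific_filter(make_beta(row[None, :]), _cohort(n))
        rec = out.set_index("class_label")
        assert rec.loc["c0", "ovr_q"] < 0.05
        assert not bool(rec.loc["c0", "passes"])

    def test_small_class_is_skipped_with_warning(self):
        samples = make_samples(["tumor"] * 12,
                               classes=["a"] * 10 + ["b"] * 2)
        beta = make_beta(np.random.default_rng(3).random((4, 12)))
        out = ovr_specific_filter(beta, samples)
        assert set(out["class_label"]) == {"a"}
        assert any("skipped" in w for w in out.attrs["warnings"])


class TestShapleyRank:
    def _informative_fixture(self, seed, n_noise=50):
        # two classes: the informative probe explains the labels completely,
        # so noise probes earn attribution only through overfitting
        rng = np.random.default_rng(seed)
        n = 90
        classes = [f"c{min(i // 30, 1)}" for i in range(n)]
        informative = np.where(np.char.equal(classes, "c0"), 0.85, 0.15)
        informative = np.clip(informative + 0.03 * rng.standard_normal(n), 0, 1)
        noise = rng.random((n_noise, n))
        beta = make_beta(np.vstack([informative, noise]),
                         probes=["cgINF"] + [f"cgN{i:02d}" for i in range(n_noise)])
        samples = make_samples(["tumor"] * n, classes=classes)
        return beta, samples

    def test_perfect_separator_ranks_first(self):
        wins = 0
        for seed in range(3):
            beta, samples = self._informative_fixture(seed)
            rank = shapley_rank(beta, samples, list(beta.probe_ids),
                                seed=seed, cohort=None)
            wins += rank["probe_id"].iloc[0] == "cgINF"
        assert wins == 3

    def test_all_noise_has_no_dominant_feature(self):
        rng = np.random.default_rng(7)
        beta = make_beta(rng.random((30, 90)))
        samples = make_samples(["tumor"] * 90,
                               classes=[f"c{i // 30}" for i in range(90)])
        rank = shapley_rank(beta, samples, list(beta.probe_ids), seed=7, cohort=None)
        assert rank["importance"].max() < 10 * max(rank["importance"].median(), 1e-9)

    def test_duplicated_informative_probe_shares_credit(self):
        beta, samples = self._informative_fixture(11)
        dup = beta.values.copy()
        dup.loc["cgDUP"] = dup.loc["cgINF"]
        beta2 = eo.BetaMatrix(dup)
        r1 = shapley_rank(beta, samples, list(beta.probe_ids), seed=11, cohort=None)
        r2 = shapley_rank(beta2, samples, list(beta2.probe_ids), seed=11, cohort=None)
        imp1 = r1.set_index("probe_id")["importance"]
        imp2 = r2.set_index("probe_id")["importance"]
        assert imp2["cgINF"] + imp2["cgDUP"] >= 0.8 * imp1["cgINF"]
        noise_max = imp2.drop(["cgINF", "cgDUP"]).max()
        assert imp2["cgINF"] > noise_max and imp2["cgDUP"] > noise_max

    def test_ranking_stable_across_seeds(self, small_bundle, qc_beta):
        bundle, truth = small_bundle
        beta, _ = qc_beta
        reg = truth.regions
        drivers = set(truth.planted_epidriver_genes)
        cand = sorted(reg.loc[reg["gene_id"].isin(drivers)
                              & reg["probe_id"].isin(beta.probe_ids), "probe_id"].unique())
        passing = ovr_specific_filter(beta, bundle.samples, cand)
        probes = sorted(passing.loc[passing["passes"], "probe_id"].unique())
        r1 = shapley_rank(beta, bundle.samples, probes, seed=1, cohort=None)
        r2 = shapley_rank(beta, bundle.samples, probes, seed=2, cohort=None)
        merged = r1.merge(r2, on="probe_id")
        rho = stats.spearmanr(merged["importance_x"], merged["importance_y"]).statistic
        assert rho >= 0.8


class TestPlateau:
    def test_hand_traced_example(self):
        acc = [0.60, 0.80, 0.90, 0.95, 0.954, 0.955]
        assert select_plateau_k(acc, epsilon=0.005, patience=2) == 4

    def test_never_plateaus_returns_full_length(self):
        acc = [0.1 + 0.05 * k for k in range(8)]
        assert select_plateau_k(acc, epsilon=0.005, patience=2) == 8

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            acc = np.minimum(1.0, np.sort(rng.random(10)) + rng.normal(0, 0.01, 10))
            k_small = select_plateau_k(list(acc), epsilon=0.002, patience=2)
            k_large = select_plateau_k(list(acc), epsilon=0.05, patience=2)
            assert k_large <= k_small

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            select_plateau_k([], 0.005, 2)
        with pytest.raises(ValidationError):
            select_plateau_k([0.5], -1.0, 2)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=15),
    st.floats(min_value=1e-4, max_value=0.2),
    st.floats(min_value=1e-4, max_value=0.2),
    st.integers(min_value=1, max_value=4),
)
def test_plateau_k_bounds_and_epsilon_monotonicity(acc, eps_a, eps_b, patience):
    k1 = select_plateau_k(acc, epsilon=min(eps_a, eps_b), patience=patience)
    k2 = select_plateau_k(acc, epsilon=max(eps_a, eps_b), patience=patience)
    assert 1 <= k2 <= k1 <= len(acc)  # a laxer floor stops earlier or equal


def test_select_markers_recovers_planted_panel(small_bundle, qc_beta):
    bundle, truth = small_bundle
    beta, _ = qc_beta
    reg = truth.regions
    drivers = set(truth.planted_epidriver_genes)
    cand = sorted(reg.loc[reg["gene_id"].isin(drivers)
                          & reg["probe_id"].isin(beta.probe_ids), "probe_id"].unique())
    split = eo.split_cohort(bundle.samples, seed=0)
    candidates, ranking = select_markers(beta, split, cand, seed=0)
    planted = sorted(p for ps in truth.planted_marker_probes.values() for p in ps)
    assert sorted(ranking.ranking["probe_id"].head(len(planted))) == planted
    assert set(ranking.panel) <= set(ranking.ranking["probe_id"])
    assert (np.diff(ranking.ranking["importance"]) <= 1e-12).all()
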