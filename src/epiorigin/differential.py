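"""Differential methylation and expression between tumor and normal tissue.

Methylation: per-probe two-sided Mann-Whitney U (exact enumeration when both
groups have <= 8 samples, tie-corrected normal approximation otherwise) with
the joint significance gate q < 0.05 and |delta beta| > 0.2, delta beta being
the tumor-minus-normal mean, so "hyper" means hypermethylated in tumor.

Expression: counts are scaled to counts-per-million, transformed to
log2(CPM + 1), and tested with a moderated two-sample t-statistic whose
per-gene variance is shrunk halfway toward the mean variance over all genes;
the gate is q < 0.05 and |log2FC| > 2.

All p-values are Benjamini-Hochberg adjusted within the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .omics_io import BetaMatrix, CountMatrix, SampleSheet, ValidationError

DELTA_BETA_GATE = 0.2
LOG2FC_GATE = 2.0
Q_GATE = 0.05
EXACT_MAX_N = 8  # exact rank-sum enumeration when both groups are this size or less
SHRINKAGE_WEIGHT = 0.5


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _contrast_groups(samples: SampleSheet, group_by: str = "condition",
                     class_label: str | None = None) -> tuple[pd.Index, pd.Index]:
    t = samples.table
    if class_label is not None:
        t = t[t["class_label"] == class_label]
    if group_by != "condition":
        raise ValidationError(f"unsupported contrast {group_by!r}; only tumor-vs-normal is defined")
    g1 = t.index[t["condition"] == "tumor"]
    g2 = t.index[t["condition"] == "normal"]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("both contrast groups need at least 2 samples")
    return g1, g2


def diff_methylation(beta: BetaMatrix, samples: SampleSheet,
                     group_by: str = "condition",
                     class_label: str | None = None,
                     method: str = "auto") -> pd.DataFrame:
    """Per-probe rank-sum test of tumor vs normal beta values.

    Requires a complete matrix (run QC first).  Returns one record per probe
    with delta_beta, p, q, significance and hyper/hypo direction.  ``method``
    is "auto" (exact enumeration when both groups have <= 8 samples,
    tie-corrected normal approximation otherwise), "exact" or "asymptotic".
    """
    if beta.values.isna().any().any():
        raise ValidationError("beta matrix contains missing values; impute first")
    g1, g2 = _contrast_groups(samples, group_by, class_label)
    g1 = [s for s in g1 if s in beta.sample_ids]
    g2 = [s for s in g2 if s in beta.sample_ids]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("both contrast groups need at least 2 samples present in beta")
    x = beta.values[g1].to_numpy()
    y = beta.values[g2].to_numpy()
    if method == "auto":
        method = "exact" if max(len(g1), len(g2)) <= EXACT_MAX_N else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    delta = x.mean(axis=1) - y.mean(axis=1)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "delta_beta": delta,
            "p": p,
            "q": q,
            "significant": (q < Q_GATE) & (np.abs(delta) > DELTA_BETA_GATE),
            "direction": np.where(delta > 0, "hyper", "hypo"),
        }
    )
    return out


def log2_cpm(counts: CountMatrix) -> pd.DataFrame:
    """log2(counts-per-million + 1); zero-depth samples map to all zeros."""
    v = counts.values.to_numpy(dtype=float)
    depth = v.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = np.where(depth > 0, v / depth * 1e6, 0.0)
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.gene_ids, columns=counts.sample_ids)


def diff_expression(counts: CountMatrix, samples: SampleSheet,
                    group_by: str = "condition",
                    class_label: str | None = None) -> pd.DataFrame:
    """Moderated two-sample test on log2(CPM+1), tumor vs normal."""
    g1, g2 = _contrast_groups(samples, group_by, class_label)
    g1 = [s for s in g1 if s in counts.sample_ids]
    g2 = [s for s in g2 if s in counts.sample_ids]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("both contrast groups need at least 2 samples present in counts")
    expr = log2_cpm(counts)
    x = expr[g1].to_numpy()
    y = expr[g2].to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (1.0 - SHRINKAGE_WEIGHT) * s2 + SHRINKAGE_WEIGHT * s2_prior
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)

    # genes with zero counts in every sample of both groups: flat by contract
    dead = (counts.values[g1].to_numpy().sum(axis=1) + counts.values[g2].to_numpy().sum(axis=1)) == 0
    log2fc = np.where(dead, 0.0, log2fc)
    p = np.where(dead, 1.0, p)

    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": (q < Q_GATE) & (np.abs(log2fc) > LOG2FC_GATE),
        }
    )
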