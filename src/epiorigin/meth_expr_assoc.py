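"""Region-windowed CpG-to-gene annotation and methylation-expression models.

CpGs are assigned to genes strand-aware: ``upstream_1500`` covers 1-1500 bp
5' of the TSS (excluding the TSS base), ``downstream_1500`` covers 0-1500 bp
3' of the TSS (including it), ``gene_body`` the rest of the span between TSS
and TES; probes inside no gene window get a single intergenic (igr) record.
Within one gene the precedence is upstream > downstream > gene body; a probe
may map to several genes.

For each (probe, gene, region) pair the expression of the gene
(log2(CPM+1)) is regressed on the probe's beta value across tumor samples,
either plain or with the cancer type (class label) as a categorical
covariate; p-values come from the methylation slope's t-statistic and are BH
adjusted within each (region, model) family.  A permutation null reruns the
cancer-type-corrected gene-level analysis on column-shuffled methylation
profiles (gene-level methylation = mean beta over the gene's assigned
probes) and summarizes how many "significant" genes arise by chance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, log2_cpm
from .omics_io import BetaMatrix, CountMatrix, GeneModel, ProbeManifest, SampleSheet, ValidationError

UPSTREAM_BP = 1500
DOWNSTREAM_BP = 1500
REGIONS = ("upstream_1500", "downstream_1500", "gene_body", "igr")
MIN_SAMPLES_PER_MODEL = 3
Q_GATE = 0.05


def annotate_regions(manifest: ProbeManifest, genes: GeneModel) -> pd.DataFrame:
    """Strand-aware region assignment of every probe to nearby genes."""
    man = manifest.table
    rows: list[tuple[str, str | None, str]] = []
    genes_by_chrom = {c: t for c, t in genes.table.groupby("chrom")}
    for probe_id, prow in man.iterrows():
        gt = genes_by_chrom.get(prow["chrom"])
        hit = False
        if gt is not None:
            pos = prow["pos"]
            strand = gt["strand"].to_numpy()
            tss = gt["tss"].to_numpy()
            tes = gt["tes"].to_numpy()
            sgn = np.where(strand == "+", 1, -1)
            d5 = (tss - pos) * sgn  # >0: probe is 5' of the TSS
            upstream = (d5 >= 1) & (d5 <= UPSTREAM_BP)
            downstream = (-d5 >= 0) & (-d5 <= DOWNSTREAM_BP)
            in_span = ((pos >= np.minimum(tss, tes)) & (pos <= np.maximum(tss, tes)))
            body = in_span & ~downstream & ~upstream
            for i, gid in enumerate(gt.index):
                if upstream[i]:
                    rows.append((probe_id, gid, "upstream_1500"))
                    hit = True
                elif downstream[i]:
                    rows.append((probe_id, gid, "downstream_1500"))
                    hit = True
                elif body[i]:
                    rows.append((probe_id, gid, "gene_body"))
                    hit = True
        if not hit:
            rows.append((probe_id, None, "igr"))
    out = pd.DataFrame(rows, columns=["probe_id", "gene_id", "region"])
    if out.duplicated(["probe_id", "gene_id"]).any():  # pragma: no cover - by construction
        raise ValidationError("duplicate (probe, gene) assignment")
    return out


def _demean(mat: np.ndarray, class_codes: np.ndarray | None) -> np.ndarray:
    """Residualize rows on the intercept or on class indicators."""
    if class_codes is None:
        return mat - mat.mean(axis=1, keepdims=True)
    out = mat.astype(float).copy()
    for code in np.unique(class_codes):
        cols = class_codes == code
        out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
    return out


def _slope_test(x: np.ndarray, y: np.ndarray, class_codes: np.ndarray | None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Row-wise OLS of y on x (optionally class-adjusted, Frisch-Waugh)."""
    n = x.shape[1]
    n_covs = 1 if class_codes is None else len(np.unique(class_codes))
    df = n - n_covs - 1
    xc = _demean(x, class_codes)
    yc = _demean(y, class_codes)
    sxx = (xc * xc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        rss = (yc * yc).sum(axis=1) - np.where(sxx > 0, sxy**2 / sxx, 0.0)
        sigma2 = np.clip(rss, 0.0, None) / max(df, 1)
        se = np.sqrt(sigma2 / np.where(sxx > 0, sxx, np.nan))
        t = slope / se
    p = np.where(np.isnan(t), np.nan,
                 np.where(np.isinf(t) | (se == 0), 0.0, 2.0 * stats.t.sf(np.abs(t), max(df, 1))))
    return slope, t, p, df


def fit_association(
    beta: BetaMatrix,
    counts: CountMatrix,
    samples: SampleSheet,
    assignments: pd.DataFrame,
    model: str = "type_corrected",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(probe, gene, region) linear models of expression on methylation.

    Returns (association records, gene-level summary).  Tumor samples
    present in both omics enter the models; ``model`` is ``plain`` or
    ``type_corrected`` (class label as categorical covariate).
    """
    if model not in ("plain", "type_corrected"):
        raise ValidationError(f"unknown model {model!r}")
    tumor = [s for s in samples.tumor_samples()
             if s in set(beta.sample_ids) and s in set(counts.sample_ids)]
    if len(tumor) < MIN_SAMPLES_PER_MODEL:
        raise ValidationError("fewer than 3 tumor samples with both omics")
    codes = None
    if model == "type_corrected":
        codes = pd.Categorical(samples.table.loc[tumor, "class_label"]).codes

    expr = log2_cpm(counts)[tumor]
    bmat = beta.values[tumor]
    pairs = assignments[
        assignments["gene_id"].notna()
        & (assignments["region"] != "igr")
        & assignments["probe_id"].isin(bmat.index)
        & assignments["gene_id"].isin(expr.index)
    ].reset_index(drop=True)
    if len(pairs) == 0:
        empty = pd.DataFrame(columns=["probe_id", "gene_id", "region", "beta_coef",
                                      "p", "q", "sign", "model", "skipped", "reason"])
        return empty, pd.DataFrame(columns=["gene_id", "model", "n_cpg", "n_sig",
                                            "n_pos", "n_neg", "any_significant"])

    x = bmat.loc[pairs["probe_id"]].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("beta matrix contains missing values; impute first")
    y = expr.loc[pairs["gene_id"]].to_numpy(dtype=float)
    slope, _, p, _ = _slope_test(x, y, codes)

    skipped = ~np.isfinite(slope)  # zero beta variance after adjustment
    rec = pairs.assign(
        beta_coef=slope,
        p=p,
        q=np.nan,
        sign=np.where(slope >= 0, "+", "-"),
        model=model,
        skipped=skipped,
        reason=np.where(skipped, "zero beta variance", ""),
    )
    for region in rec.loc[~skipped, "region"].unique():
        fam = (~skipped) & (rec["region"] == region).to_numpy()
        rec.loc[fam, "q"] = bh_adjust(rec.loc[fam, "p"].to_numpy())

    ok = rec[~rec["skipped"]]
    sig = ok[ok["q"] < Q_GATE]
    summary = (
        ok.groupby("gene_id")
        .agg(n_cpg=("probe_id", "size"))
        .join(sig.groupby("gene_id").agg(
            n_sig=("probe_id", "size"),
            n_pos=("sign", lambda s: int((s == "+").sum())),
            n_neg=("sign", lambda s: int((s == "-").sum())),
        ))
        .reset_index()
    )
    for col in ("n_sig", "n_pos", "n_neg"):
        summary[col] = pd.to_numeric(summary[col], errors="coerce").fillna(0).astype(int)
    summary["model"] = model
    summary["any_significant"] = summary["n_sig"] > 0
    return rec, summary


@dataclass
class PermutationSummary:
    n_perm: int
    observed_significant_genes: int
    null_mean: float
    null_sd: float
    null_counts: list[int]

    def to_dict(self) -> dict:
        return asdict(self)


def gene_level_beta(beta: BetaMatrix, assignments: pd.DataFrame) -> pd.DataFrame:
    """Mean beta over each gene's assigned probes (whole-window profile)."""
    pairs = assignments[assignments["gene_id"].notna()
                        & (assignments["region"] != "igr")
                        & assignments["probe_id"].isin(beta.values.index)]
    mat = beta.values.loc[pairs["probe_id"]].to_numpy(dtype=float)
    return (
        pd.DataFrame(mat, index=pairs["gene_id"].to_numpy(), columns=beta.values.columns)
        .groupby(level=0)
        .mean()
    )


def permutation_null(
    beta: BetaMatrix,
    counts: CountMatrix,
    samples: SampleSheet,
    assignments: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    permutations: list[np.ndarray] | None = None,
) -> PermutationSummary:
    """Shuffle methylation profiles across samples and recount significant genes.

    Gene-level methylation (mean beta over assigned probes) is regressed on
    expression with the cancer-type-corrected model; each iteration permutes
    the sample columns of the methylation matrix only (expression and class
    labels stay fixed).  ``permutations`` overrides the seeded draws (test
    hook, e.g. forcing the identity permutation).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    tumor = [s for s in samples.tumor_samples()
             if s in set(beta.sample_ids) and s in set(counts.sample_ids)]
    codes = pd.Categorical(samples.table.loc[tumor, "class_label"]).codes
    gb = gene_level_beta(beta, assignments)[tumor]
    common = [g for g in gb.index if g in set(counts.gene_ids)]
    gb = gb.loc[common]
    expr = log2_cpm(counts).loc[common, tumor]
    x0 = gb.to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float)
    if np.isnan(x0).any():
        raise ValidationError("beta matrix contains missing values; impute first")

    def count_significant(x: np.ndarray) -> int:
        slope, _, p, _ = _slope_test(x, y, codes)
        valid = np.isfinite(slope)
        if not valid.any():
            return 0
        q = bh_adjust(p[valid])
        return int((q < Q_GATE).sum())

    observed = count_significant(x0)
    rng = np.random.default_rng(seed)
    null_counts = []
    for i in range(n_perm):
        perm = permutations[i] if permutations is not None else rng.permutation(x0.shape[1])
        null_counts.append(count_significant(x0[:, perm]))
    arr = np.asarray(null_counts, dtype=float)
    return PermutationSummary(
        n_perm=n_perm,
        observed_significant_genes=observed,
        null_mean=float(arr.mean()),
        null_sd=float(arr.std(ddof=0)),
        null_counts=[int(c) for c in null_counts],
    )
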