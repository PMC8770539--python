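"""Probe-level quality filtering and KNN imputation of beta values.

Filtering removes, in this order of attribution, probes on chrX/chrY,
SNP-overlapping probes, multi-mapping probes and probes with a missing
fraction strictly greater than 0.5; each probe is counted once under the
first matching rule.  Imputation fills the remaining missing entries with
the mean of the k nearest probes (Euclidean distance over pairwise-complete
samples), never touching observed values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .omics_io import BetaMatrix, ProbeManifest, ValidationError

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
DEFAULT_K = 10


@dataclass
class FilterReport:
    removed_xy: int = 0
    removed_snp: int = 0
    removed_multimap: int = 0
    removed_missing: int = 0
    kept: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest) -> tuple[BetaMatrix, FilterReport]:
    """Remove invalid or ambiguous CpG probes; preserve the remaining order."""
    missing_probes = [p for p in beta.probe_ids if p not in set(manifest.probe_ids)]
    if missing_probes:
        raise ValidationError(f"probes absent from the manifest: {missing_probes[:5]}")
    man = manifest.table.loc[beta.probe_ids]
    is_xy = man["chrom"].isin(SEX_CHROMS).to_numpy()
    is_snp = man["snp_flag"].to_numpy()
    is_multi = man["multimap_flag"].to_numpy()
    miss_frac = beta.values.isna().mean(axis=1).to_numpy()
    too_missing = miss_frac > 0.5  # strictly greater, 0.5 itself is kept

    report = FilterReport()
    drop = np.zeros(len(man), dtype=bool)
    for mask, attr in (
        (is_xy, "removed_xy"),
        (is_snp, "removed_snp"),
        (is_multi, "removed_multimap"),
        (too_missing, "removed_missing"),
    ):
        new = mask & ~drop
        setattr(report, attr, int(new.sum()))
        drop |= mask
    report.kept = int((~drop).sum())
    return BetaMatrix(beta.values.loc[~drop].copy()), report


def knn_impute(beta: BetaMatrix, k: int = DEFAULT_K) -> BetaMatrix:
    """Fill missing beta values from the k most similar probes.

    For a missing (probe, sample) cell, the donors are the k probes nearest
    in Euclidean distance computed over pairwise-complete samples that are
    observed at that sample; the imputed value is their uniform mean.
    Observed entries are returned bit-identical.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    vals = beta.values
    if not vals.isna().any().any():
        return beta.copy()
    all_missing_samples = vals.columns[vals.isna().all(axis=0)]
    if len(all_missing_samples):
        raise ValidationError(
            f"samples with all values missing cannot be imputed: {list(all_missing_samples)[:5]}"
        )
    k_eff = min(k, len(vals) - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    filled = imputer.fit_transform(vals.to_numpy())
    if filled.shape[0] != vals.shape[0]:  # pragma: no cover - KNNImputer keeps rows
        raise ValidationError("imputation dropped probes unexpectedly")
    if np.isnan(filled).any():
        raise ValidationError("imputation left missing values (no eligible donors)")
    out = vals.to_numpy().copy()
    mask = np.isnan(out)
    out[mask] = np.clip(filled[mask], 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(out, index=vals.index, columns=vals.columns))


def qc(beta: BetaMatrix, manifest: ProbeManifest, k: int = DEFAULT_K) -> tuple[BetaMatrix, FilterReport]:
    """filter_probes followed by knn_impute (the standard QC stage)."""
    filtered, report = filter_probes(beta, manifest)
    return knn_impute(filtered, k=k), report
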