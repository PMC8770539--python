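"""Tabular input/output and shared domain types.

All pipeline stages exchange data through the small set of containers defined
here: a methylation beta matrix (probes x samples, values in [0, 1] with an
explicit missingness mask), an RNA count matrix, the probe manifest and gene
model needed for region annotation, the sample sheet (the single source of
truth for class labels, tumor/normal condition and train/test cohort), a
metabolic reaction table and a protein-protein interaction edge list.

File conventions
----------------
* ``beta.tsv``     : column 1 ``probe_id``, remaining columns sample ids;
                     decimal values or the literal token ``NA`` for missing.
* ``counts.tsv``   : column 1 ``gene_id``, remaining columns sample ids;
                     non-negative integers.
* ``manifest.csv`` : probe_id,chrom,pos,island_relation,snp_flag,multimap_flag
* ``genes.tsv``    : gene_id,chrom,strand,tss,tes   (1-based, inclusive;
                     minus-strand genes have tss > tes)
* ``samples.tsv``  : sample_id,class_label,condition,pair_id,cohort
* ``reactions.tsv``: reaction_id,enzyme_gene,substrates,products
                     (metabolite ids ";"-joined)
* ``ppi.tsv``      : gene_a,gene_b,weight

Validation is total: nothing is silently dropped.  ``read_bundle`` subsets
the matrices to the sample sheet and itemizes every dropped or unknown id in
its report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
CONDITIONS = ("tumor", "normal")
COHORTS = ("train", "test", "external", "")
NA_TOKEN = "NA"


class ValidationError(ValueError):
    """Raised when an input file or container violates its schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class BetaMatrix:
    """Methylation beta values, probes x samples; NaN encodes missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bool(np.nansum(bad)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}: {arr[r, c]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy())


@dataclass
class CountMatrix:
    """Read counts, genes x samples; non-negative integers."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("count matrix contains missing values")
        if (arr.astype(float) < 0).any() or not np.allclose(arr, np.round(arr.astype(float))):
            raise ValidationError("counts must be non-negative integers")
        self.values = self.values.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProbeManifest:
    """Probe genomic coordinates and QC flags, indexed by probe_id."""

    table: pd.DataFrame  # columns: chrom, pos, island_relation, snp_flag, multimap_flag

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe ids")
        bad = set(self.table["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise ValidationError(f"unknown island_relation values: {sorted(bad)}")
        if (self.table["pos"] < 1).any():
            raise ValidationError("probe pos must be >= 1 (1-based)")
        self.table = self.table.assign(
            pos=self.table["pos"].astype(np.int64),
            snp_flag=self.table["snp_flag"].astype(bool),
            multimap_flag=self.table["multimap_flag"].astype(bool),
        )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class GeneModel:
    """Gene coordinates, indexed by gene_id.

    1-based inclusive; strand '+' requires tss < tes, strand '-' tss > tes.
    """

    table: pd.DataFrame  # columns: chrom, strand, tss, tes

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene ids")
        if not set(self.table["strand"]) <= {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")
        t = self.table
        plus_bad = (t["strand"] == "+") & ~(t["tss"] < t["tes"])
        minus_bad = (t["strand"] == "-") & ~(t["tss"] > t["tes"])
        if plus_bad.any() or minus_bad.any():
            offender = t.index[plus_bad | minus_bad][0]
            raise ValidationError(f"inconsistent tss/tes orientation for gene {offender!r}")
        self.table = t.assign(tss=t["tss"].astype(np.int64), tes=t["tes"].astype(np.int64))

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class SampleSheet:
    """Per-sample class label, condition, pairing and cohort assignment."""

    table: pd.DataFrame  # columns: class_label, condition, pair_id, cohort

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition values: {sorted(bad)}")
        t = self.table.fillna({"pair_id": "", "cohort": ""})
        bad_cohort = set(t["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort values: {sorted(bad_cohort)}")
        paired = t[t["pair_id"] != ""]
        dup = paired.groupby(["pair_id", "condition"]).size()
        if (dup > 1).any():
            key = dup[dup > 1].index[0]
            raise ValidationError(f"pair_id {key[0]!r} occurs more than once per condition")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())

    def tumor_samples(self, cohort: str | None = None) -> pd.Index:
        t = self.table
        mask = t["condition"] == "tumor"
        if cohort is not None:
            mask &= t["cohort"] == cohort
        return t.index[mask]


@dataclass
class ReactionTable:
    """Metabolic reactions: enzyme gene plus substrate/product metabolite sets."""

    table: pd.DataFrame  # index reaction_id; columns enzyme_gene, substrates, products

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "reaction ids")
        for col in ("substrates", "products"):
            vals = self.table[col].map(lambda s: frozenset(s))
            if vals.map(len).eq(0).any():
                rid = self.table.index[vals.map(len) == 0][0]
                raise ValidationError(f"reaction {rid!r} has empty {col}")
            self.table[col] = vals


@dataclass
class EdgeList:
    """Weighted gene-gene edges; undirected unless ``directed`` is set."""

    table: pd.DataFrame  # columns gene_a, gene_b, weight
    directed: bool = False

    def __post_init__(self) -> None:
        t = self.table
        if (t["gene_a"] == t["gene_b"]).any():
            raise ValidationError("self-loops are not allowed in the edge list")
        w = t["weight"].astype(float)
        if ((w < 0) | (w > 1)).any():
            raise ValidationError("edge weights must lie in [0,1]")
        self.table = t.assign(weight=w)


@dataclass
class BundleReport:
    """Itemized account of what read_bundle dropped or flagged."""

    dropped_samples: dict[str, list[str]] = field(default_factory=dict)
    dropped_probes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Bundle:
    beta: BetaMatrix
    counts: CountMatrix
    manifest: ProbeManifest
    genes: GeneModel
    samples: SampleSheet
    reactions: ReactionTable
    ppi: EdgeList
    report: BundleReport = field(default_factory=BundleReport)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_numeric_matrix(path: Path, id_col: str, allow_na: bool) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    if raw.columns[0].lower() != id_col:
        raise ValidationError(f"{path}: first column must be {id_col!r}, got {raw.columns[0]!r}")
    raw = raw.set_index(raw.columns[0])
    out = {}
    for col in raw.columns:
        cell = raw[col].str.strip()
        numeric = pd.to_numeric(cell.mask(cell == NA_TOKEN), errors="coerce")
        bad = numeric.isna() & (cell != NA_TOKEN) & cell.notna()
        if bad.any():
            row = bad.idxmax()
            raise ValidationError(
                f"{path}: malformed numeric cell at row {row!r}, column {col!r}: {cell[row]!r}"
            )
        if not allow_na and (numeric.isna()).any():
            row = numeric.isna().idxmax()
            raise ValidationError(f"{path}: missing value at row {row!r}, column {col!r}")
        out[col] = numeric
    return pd.DataFrame(out, index=raw.index)


def read_beta(path: Path) -> BetaMatrix:
    df = _read_numeric_matrix(Path(path), "probe_id", allow_na=True)
    arr = df.to_numpy()
    bad = (arr < 0) | (arr > 1)
    if bool(np.nansum(bad)):
        r, c = np.argwhere(bad & ~np.isnan(arr))[0]
        raise ValidationError(
            f"{path}: beta value out of [0,1] at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {arr[r, c]}"
        )
    return BetaMatrix(df)


def read_counts(path: Path) -> CountMatrix:
    df = _read_numeric_matrix(Path(path), "gene_id", allow_na=False)
    arr = df.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere((arr < 0) | (arr != np.round(arr)))[0]
        raise ValidationError(
            f"{path}: count must be a non-negative integer at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {arr[r, c]}"
        )
    return CountMatrix(df.astype(np.int64))


def _read_table(path: Path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_manifest(path: Path) -> ProbeManifest:
    df = _read_table(path, ",", ["probe_id", "chrom", "pos", "island_relation", "snp_flag", "multimap_flag"])
    df = df.set_index("probe_id")
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
    df["snp_flag"] = df["snp_flag"].str.lower().isin(("true", "1", "yes"))
    df["multimap_flag"] = df["multimap_flag"].str.lower().isin(("true", "1", "yes"))
    return ProbeManifest(df[["chrom", "pos", "island_relation", "snp_flag", "multimap_flag"]])


def read_genes(path: Path) -> GeneModel:
    df = _read_table(path, "\t", ["gene_id", "chrom", "strand", "tss", "tes"])
    df = df.set_index("gene_id")
    df["tss"] = pd.to_numeric(df["tss"]).astype(np.int64)
    df["tes"] = pd.to_numeric(df["tes"]).astype(np.int64)
    return GeneModel(df[["chrom", "strand", "tss", "tes"]])


def read_samples(path: Path) -> SampleSheet:
    df = _read_table(path, "\t", ["sample_id", "class_label", "condition", "pair_id", "cohort"])
    return SampleSheet(df.set_index("sample_id")[["class_label", "condition", "pair_id", "cohort"]])


def read_reactions(path: Path) -> ReactionTable:
    df = _read_table(path, "\t", ["reaction_id", "enzyme_gene", "substrates", "products"])
    df = df.set_index("reaction_id")
    for col in ("substrates", "products"):
        df[col] = df[col].map(lambda s: frozenset(x for x in s.split(";") if x))
    return ReactionTable(df[["enzyme_gene", "substrates", "products"]])


def read_ppi(path: Path) -> EdgeList:
    df = _read_table(path, "\t", ["gene_a", "gene_b", "weight"])
    df["weight"] = pd.to_numeric(df["weight"])
    return EdgeList(df[["gene_a", "gene_b", "weight"]].reset_index(drop=True), directed=False)


DEFAULT_FILENAMES = {
    "beta": "beta.tsv",
    "counts": "counts.tsv",
    "manifest": "manifest.csv",
    "genes": "genes.tsv",
    "samples": "samples.tsv",
    "reactions": "reactions.tsv",
    "ppi": "ppi.tsv",
}


def read_bundle(paths: Mapping[str, Path] | Path) -> Bundle:
    """Read and cross-validate a full input bundle.

    ``paths`` is either a directory holding the default file names or a
    mapping with keys beta/counts/manifest/genes/samples/reactions/ppi.
    Samples absent from the sample sheet and probes absent from the manifest
    are dropped from the matrices and itemized in the report.
    """
    if not isinstance(paths, Mapping):
        base = Path(paths)
        paths = {k: base / v for k, v in DEFAULT_FILENAMES.items()}
    for key, p in paths.items():
        if not Path(p).exists():
            raise ValidationError(f"input file for {key!r} does not exist: {p}")

    beta = read_beta(paths["beta"])
    counts = read_counts(paths["counts"])
    manifest = read_manifest(paths["manifest"])
    genes = read_genes(paths["genes"])
    samples = read_samples(paths["samples"])
    reactions = read_reactions(paths["reactions"])
    ppi = read_ppi(paths["ppi"])

    report = BundleReport()

    known = set(samples.sample_ids)
    for name, mat in (("beta", beta.values), ("counts", counts.values)):
        extra = [s for s in mat.columns if s not in known]
        if extra:
            report.dropped_samples[name] = extra
            mat.drop(columns=extra, inplace=True)

    unknown_probes = [p for p in beta.probe_ids if p not in set(manifest.probe_ids)]
    if unknown_probes:
        report.dropped_probes = unknown_probes
        beta.values.drop(index=unknown_probes, inplace=True)

    known_genes = set(genes.gene_ids)
    external_enzymes = sorted(set(reactions.table["enzyme_gene"]) - known_genes)
    if external_enzymes:
        report.warnings.append(
            f"{len(external_enzymes)} reaction enzyme genes absent from the gene model: "
            f"{external_enzymes[:5]}"
        )

    return Bundle(beta, counts, manifest, genes, samples, reactions, ppi, report)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame | Mapping | Sequence, path: Path, format: str = "tsv") -> Path:
    """Write a result table/report; round-trips field-for-field.

    ``format`` one of tsv, csv, json.  DataFrames keep their index only when
    it is named.
    """
    if records is None:
        raise ValidationError("records must not be None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        if isinstance(records, pd.DataFrame):
            payload = records.to_dict(orient="records")
        else:
            payload = records
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
        return path
    if format not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep=sep, index=df.index.name is not None, float_format="%.12g", na_rep=NA_TOKEN)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_written_table(path: Path, format: str = "tsv"):
    """Inverse of write_table (used to verify round-trips)."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    sep = "\t" if format == "tsv" else ","
    return pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)


def write_beta(beta: BetaMatrix, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = beta.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.12g")
    return path


def write_counts(counts: CountMatrix, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = counts.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    return path


def write_bundle(bundle: Bundle, out_dir: Path) -> dict[str, Path]:
    """Write every bundle component under ``out_dir`` with default names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in DEFAULT_FILENAMES.items()}
    write_beta(bundle.beta, paths["beta"])
    write_counts(bundle.counts, paths["counts"])

    man = bundle.manifest.table.copy()
    man.index.name = "probe_id"
    man.to_csv(paths["manifest"])

    gen = bundle.genes.table.copy()
    gen.index.name = "gene_id"
    gen.to_csv(paths["genes"], sep="\t")

    sam = bundle.samples.table.copy()
    sam.index.name = "sample_id"
    sam.to_csv(paths["samples"], sep="\t")

    rx = bundle.reactions.table.copy()
    rx.index.name = "reaction_id"
    rx["substrates"] = rx["substrates"].map(lambda s: ";".join(sorted(s)))
    rx["products"] = rx["products"].map(lambda s: ";".join(sorted(s)))
    rx.to_csv(paths["reactions"], sep="\t")

    bundle.ppi.table.to_csv(paths["ppi"], sep="\t", index=False, float_format="%.12g")
    return paths
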