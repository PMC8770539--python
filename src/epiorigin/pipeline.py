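"""End-to-end orchestration with a single config and a content-hashed manifest.

``run_pipeline`` executes the nine stages in dependency order::

    simulate -> qc -> diff_meth / diff_expr -> assoc -> epidriver
             -> markers -> classifier -> report

writing every stage's outputs under the run directory and recording a
manifest with the seed, the resolved configuration and a sha256 hash of
each input/output file, so a rerun with an identical config is
bit-identical.  Stages can be toggled; a disabled dependency aborts with
the name of the stage that needs it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import classifier as clf
from . import differential, epidriver_network, marker_selection, meth_expr_assoc, preprocess
from .omics_io import (
    BetaMatrix,
    Bundle,
    SampleSheet,
    ValidationError,
    read_bundle,
    write_beta,
    write_bundle,
    write_table,
)
from .synthetic_data import SimulationConfig, generate_bundle

log = logging.getLogger("epiorigin")

STAGES = ("simulate", "qc", "diff_meth", "diff_expr", "assoc",
          "epidriver", "markers", "classifier", "report")
STAGE_DEPS = {
    "qc": ("simulate",),
    "diff_meth": ("qc",),
    "diff_expr": ("simulate",),
    "assoc": ("qc",),
    "epidriver": ("diff_expr", "assoc"),
    "markers": ("qc", "epidriver"),
    "classifier": ("markers",),
    "report": ("classifier",),
}


@dataclass
class PipelineConfig:
    """All stage parameters; seeds are mandatory for stochastic stages."""

    seed: int = 0
    input_dir: str | None = None  # read an existing bundle instead of simulating
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    knn_k: int = 10
    tau: float = 0.6
    min_module_size: int = 10
    cut_height: float = 0.3
    key_fraction: float = 0.10
    n_perm: int = 100
    epsilon: float = 0.005
    patience: int = 2
    max_panel_k: int = 12
    split_ratio: float = 0.7
    tree_grid: tuple[int, ...] = clf.DEFAULT_TREE_GRID
    n_boot: int = 1000
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if not (0 < self.tau < 1 and 0 < self.cut_height < 2 and 0 < self.key_fraction <= 1):
            raise ValidationError("tau/cut_height/key_fraction outside documented bounds")
        if not (0 < self.split_ratio < 1) or self.epsilon <= 0 or self.patience < 1:
            raise ValidationError("split_ratio/epsilon/patience outside documented bounds")
        if self.n_perm < 1 or self.knn_k < 1 or self.max_panel_k < 1:
            raise ValidationError("n_perm/knn_k/max_panel_k must be >= 1")
        for s in self.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in payload and isinstance(payload["simulation"], dict):
            sim = dict(payload["simulation"])
            if isinstance(sim.get("n_planted_markers_per_class"), list):
                sim["n_planted_markers_per_class"] = tuple(sim["n_planted_markers_per_class"])
            payload["simulation"] = SimulationConfig(**sim)
        if "tree_grid" in payload:
            payload["tree_grid"] = tuple(payload["tree_grid"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["n_planted_markers_per_class"] = list(
            np.atleast_1d(d["simulation"]["n_planted_markers_per_class"]).tolist()
        )
        d["tree_grid"] = list(d["tree_grid"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def cluster_heatmap(beta_subset: pd.DataFrame, samples: SampleSheet,
                    image_path: Path | None = None) -> dict:
    """Row-z-scored matrix ordered by complete-linkage Euclidean clustering.

    Constant rows z-score to all zeros (with a warning); leaf order is
    deterministic, ties resolved by id via lexicographic input ordering.
    Returns the ordered matrix plus row/column dendrogram leaf orders.
    """
    if beta_subset.shape[0] < 2 or beta_subset.shape[1] < 2:
        raise ValidationError("heatmap needs >= 2 rows and >= 2 columns")
    df = beta_subset.sort_index(axis=0).sort_index(axis=1)
    arr = df.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    warnings = []
    if (sd == 0).any():
        warnings.append(f"{int((sd == 0).sum())} constant rows z-scored to zeros")
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    def order(mat: np.ndarray) -> list[int]:
        link = linkage(pdist(mat, metric="euclidean"), method="complete")
        return [int(i) for i in leaves_list(link)]

    row_order = order(z)
    col_order = order(z.T)
    ordered = pd.DataFrame(z, index=df.index, columns=df.columns).iloc[row_order, col_order]
    result = {
        "matrix": ordered,
        "row_order": [str(df.index[i]) for i in row_order],
        "col_order": [str(df.columns[i]) for i in col_order],
        "warnings": warnings,
    }
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-3, vmax=3, interpolation="nearest")
        ax.set_xlabel("samples (clustered)")
        ax.set_ylabel("CpG probes (clustered)")
        ax.set_yticks(range(len(ordered.index)), list(ordered.index), fontsize=6)
        ax.set_xticks([])
        fig.colorbar(im, ax=ax, label="beta z-score")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120, metadata={"Software": "epiorigin"})
        plt.close(fig)
        result["image"] = str(image_path)
    return result


def run_pipeline(cfg: PipelineConfig, out_dir: Path) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": cfg.to_dict(), "stages": []}
    produced: dict[str, list[Path]] = {}
    enabled = cfg.stages

    def require(stage: str) -> None:
        for dep in STAGE_DEPS.get(stage, ()):
            if dep == "simulate" and cfg.input_dir:
                continue  # a provided bundle satisfies the simulate dependency
            if not enabled.get(dep, False):
                raise ValidationError(
                    f"stage {stage!r} requires stage {dep!r}, which is disabled"
                )

    def record(stage: str, t0: float, inputs: list[Path], outputs: list[Path],
               info: dict | None = None) -> None:
        produced[stage] = outputs
        manifest["stages"].append({
            "stage": stage,
            "wall_time_s": round(time.time() - t0, 3),
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            **(info or {}),
        })
        log.info("stage %-10s done in %.2fs (%d outputs)", stage, time.time() - t0,
                 len(outputs))

    # ---- simulate / load -------------------------------------------------
    t0 = time.time()
    if enabled["simulate"]:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        bundle, truth = generate_bundle(sim_cfg)
        bdir = out / "bundle"
        paths = write_bundle(bundle, bdir)
        truth_path = truth.to_json(bdir / "truth.json")
        record("simulate", t0, [], sorted(paths.values()) + [truth_path],
               {"n_probes": len(bundle.beta.probe_ids), "n_samples": len(bundle.samples.sample_ids)})
    elif cfg.input_dir:
        bundle = read_bundle(Path(cfg.input_dir))
        truth = None
    else:
        raise ValidationError("either enable the simulate stage or provide input_dir")

    results: dict = {"bundle": bundle}

    # ---- qc --------------------------------------------------------------
    if enabled["qc"]:
        require("qc")
        t0 = time.time()
        beta_qc, filter_report = preprocess.qc(bundle.beta, bundle.manifest, k=cfg.knn_k)
        p1 = write_beta(beta_qc, out / "beta_qc.tsv")
        p2 = write_table(filter_report.to_dict(), out / "filter_report.json", "json")
        record("qc", t0, [], [p1, p2], {"kept": filter_report.kept})
        results["beta_qc"] = beta_qc

    # ---- differential ----------------------------------------------------
    if enabled["diff_meth"]:
        require("diff_meth")
        t0 = time.time()
        dm = differential.diff_methylation(results["beta_qc"], bundle.samples)
        record("diff_meth", t0, [], [write_table(dm, out / "diff_meth.tsv")],
               {"significant": int(dm["significant"].sum())})
        results["diff_meth"] = dm
    if enabled["diff_expr"]:
        require("diff_expr")
        t0 = time.time()
        de = differential.diff_expression(bundle.counts, bundle.samples)
        record("diff_expr", t0, [], [write_table(de, out / "diff_expr.tsv")],
               {"significant": int(de["significant"].sum())})
        results["diff_expr"] = de

    # ---- association -----------------------------------------------------
    if enabled["assoc"]:
        require("assoc")
        t0 = time.time()
        assignments = meth_expr_assoc.annotate_regions(bundle.manifest, bundle.genes)
        rec_c, sum_c = meth_expr_assoc.fit_association(
            results["beta_qc"], bundle.counts, bundle.samples, assignments, "type_corrected")
        rec_p, sum_p = meth_expr_assoc.fit_association(
            results["beta_qc"], bundle.counts, bundle.samples, assignments, "plain")
        perm = meth_expr_assoc.permutation_null(
            results["beta_qc"], bundle.counts, bundle.samples, assignments,
            n_perm=cfg.n_perm, seed=cfg.seed)
        outs = [
            write_table(assignments, out / "region_assignments.tsv"),
            write_table(pd.concat([rec_c, rec_p], ignore_index=True), out / "assoc_cpg.tsv"),
            write_table(pd.concat([sum_c, sum_p], ignore_index=True), out / "assoc_gene.tsv"),
            write_table(perm.to_dict(), out / "permutation.json", "json"),
        ]
        record("assoc", t0, [], outs,
               {"significant_genes": int(sum_c["any_significant"].sum()),
                "null_mean": perm.null_mean})
        results.update(assignments=assignments, assoc_gene=sum_c, assoc_perm=perm)

    # ---- epidriver -------------------------------------------------------
    if enabled["epidriver"]:
        require("epidriver")
        t0 = time.time()
        modules = epidriver_network.build_coexpression_modules(
            bundle.counts, bundle.samples, tau=cfg.tau,
            min_size=cfg.min_module_size, cut_height=cfg.cut_height)
        net_met = epidriver_network.build_directed_net(bundle.reactions)
        net_ppi = epidriver_network.build_directed_net(bundle.ppi)
        sc_met = epidriver_network.score_importance(
            net_met, modules, bundle.counts, bundle.samples, key_fraction=cfg.key_fraction)
        sc_ppi = epidriver_network.score_importance(
            net_ppi, modules, bundle.counts, bundle.samples, key_fraction=cfg.key_fraction)
        flags = dict(zip(results["assoc_gene"]["gene_id"], results["assoc_gene"]["any_significant"]))
        calls = epidriver_network.call_epidrivers(results["diff_expr"], sc_met, sc_ppi, flags)
        outs = [
            write_table(sc_met, out / "gene_scores_metabolic.tsv"),
            write_table(sc_ppi, out / "gene_scores_ppi.tsv"),
            write_table(calls, out / "epidrivers.tsv"),
        ]
        record("epidriver", t0, [], outs, {"epi_drivers": int(calls["epi_driver"].sum())})
        results["epidrivers"] = calls

    # ---- markers ---------------------------------------------------------
    if enabled["markers"]:
        require("markers")
        t0 = time.time()
        split = clf.split_cohort(bundle.samples, ratio=cfg.split_ratio, seed=cfg.seed)
        driver_genes = set(results["epidrivers"].loc[results["epidrivers"]["epi_driver"], "gene"])
        if not driver_genes:
            raise ValidationError("stage 'markers': no epi-driver genes were called")
        a = results["assignments"]
        cand = sorted(a.loc[a["gene_id"].isin(driver_genes)
                            & a["probe_id"].isin(results["beta_qc"].probe_ids),
                            "probe_id"].unique())
        candidates, ranking = marker_selection.select_markers(
            results["beta_qc"], split, cand, epsilon=cfg.epsilon,
            patience=cfg.patience, seed=cfg.seed, max_k=cfg.max_panel_k)
        sam = split.table.copy()
        sam.index.name = "sample_id"
        outs = [
            write_table(sam.reset_index(), out / "samples_split.tsv"),
            write_table(candidates, out / "candidates.tsv"),
            write_table(ranking.ranking, out / "ranking.tsv"),
            write_table(pd.DataFrame({"probe_id": ranking.panel}), out / "panel.tsv"),
            write_table({"cumulative_accuracy": ranking.cumulative_accuracy,
                         "selected_k": ranking.selected_k}, out / "plateau.json", "json"),
        ]
        record("markers", t0, [], outs, {"panel_size": ranking.selected_k})
        results.update(split=split, panel=ranking.panel)

    # ---- classifier ------------------------------------------------------
    if enabled["classifier"]:
        require("classifier")
        t0 = time.time()
        model = clf.train_ovr_forest(results["beta_qc"], results["split"], results["panel"],
                                     seed=cfg.seed, tree_grid=cfg.tree_grid)
        report = clf.evaluate(model, results["beta_qc"], results["split"],
                              cohort="test", n_boot=cfg.n_boot, seed=cfg.seed)
        outs = [
            model.save(out / "model.pkl"),
            write_table(report.to_dict(), out / "classifier_report.json", "json"),
        ]
        record("classifier", t0, [], outs,
               {"overall_accuracy": report.overall_accuracy})
        results.update(model=model, report=report)

    # ---- report ----------------------------------------------------------
    if enabled["report"]:
        require("report")
        t0 = time.time()
        tumor = [s for s in results["split"].tumor_samples()]
        hm = cluster_heatmap(results["beta_qc"].values.loc[results["panel"], tumor],
                             results["split"], image_path=out / "heatmap.png")
        outs = [
            write_table({"row_order": hm["row_order"], "col_order": hm["col_order"],
                         "warnings": hm["warnings"]}, out / "heatmap_order.json", "json"),
            Path(hm["image"]),
        ]
        record("report", t0, [], outs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    return results
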