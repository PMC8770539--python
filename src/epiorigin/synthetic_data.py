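"""Synthetic multi-omics bundles with known ground truth.

The generator emulates the study design the pipeline targets: paired
tumor/normal cohorts over several tissue classes profiled on an HM450-style
beta-value array plus RNA read counts, together with a probe manifest, gene
model, metabolic reaction list and PPI edge list.

Planted structure (all recorded in :class:`GroundTruth`):

* **Epi-driver genes.**  Each planted driver carries a per-tumor-sample
  methylation latent ``u``: its gene-body probe tracks ``u`` (positive
  coupling), its promoter probe tracks ``1 - u`` (negative coupling), and the
  same latent drives a tumor-only co-expression factor shared with a block of
  companion genes.  Drivers are 8-fold up-regulated in tumors; companions are
  shifted enough to make their module tumor-specific but stay below the
  differential-expression fold-change gate.  In the reaction table the
  driver's products feed four companions, continuing into a three-enzyme
  chain; in the PPI table the driver is a hub wired to every companion.
  Downstream chain enzymes and background genes also get out-edges, but
  diluted with targets outside any module, so only true drivers are enriched
  for module members among their downstream neighbours.
* **Tissue-specific marker CpGs.**  Extra gene-body probes of driver genes
  with a tight high beta in the marked class's tumors and a bimodal
  low/intermediate mixture everywhere else (identical across unmarked
  classes): the between-mode spread keeps the pooled SD over tumor samples
  above the 0.2 marker gate while the probe carries information about its
  own class only.
* **Confounded genes.**  Background genes whose expression and gene-body
  methylation both shift between classes with no within-class coupling --
  exactly the artifact a cancer-type-corrected association model must remove.
* **Nuisance probes.**  chrX/chrY, SNP-flagged, multi-mapping and
  high-missing probes that exercise the QC filters, plus ~2% random missing
  beta entries.

Counts are drawn from a Poisson-gamma (negative-binomial-style) mixture with
per-sample library scale factors; beta noise is added on the logit scale and
clipped to [0.001, 0.999].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .omics_io import (
    BetaMatrix,
    Bundle,
    BundleReport,
    CountMatrix,
    EdgeList,
    GeneModel,
    ProbeManifest,
    ReactionTable,
    SampleSheet,
    ValidationError,
)

COMPANIONS_PER_DRIVER = 11  # module size 11 >= default min_module_size 10
N_SPECIAL_PROBES = 8  # 2 chrX, 2 chrY, 2 SNP-flagged, 2 multi-mapping
MODULE_LOADING = 0.8  # co-expression factor loading (log2 units)
EXPR_NOISE_SD = 0.15  # within-condition log2 expression noise
DRIVER_LOG2FC = 3.0  # planted tumor CPM shift for drivers (|log2FC| gate is 2)
COMPANION_LOG2FC = 1.5  # tumor shift for module companions; sign alternates by module
CONFOUND_EXPR_SCALE = 1.6  # log2 class-shift scale for confounded genes
CONFOUND_BETA_SCALE = 0.3  # beta class-shift scale for confounded genes
# outside the marked class, marker-probe beta is a 50/50 mixture of two tight
# modes (unmethylated / intermediate), mirroring the bimodality of real CpGs:
# the between-mode spread keeps the pooled SD over tumor samples above the 0.2
# marker gate while both modes stay well below the marked class's level
MARKER_REST_MODES = (0.05, 0.45)
MARKER_MODE_SD = 0.02  # within-mode beta noise


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic bundle.

    ``n_planted_markers_per_class`` is an int applied to every class or one
    int per class; the default (2, 1, 1, 1, 1) yields six markers hosted in
    five driver genes over five classes.
    """

    n_classes: int = 5
    n_pairs_per_class: int = 40
    n_probes: int = 1000
    n_genes: int = 200
    n_planted_epidrivers: int = 10
    n_planted_markers_per_class: int | Sequence[int] = (2, 1, 1, 1, 1)
    coupling_r: float = 0.7
    delta_beta_effect: float = 0.3
    marker_separation: float = 0.4
    noise_sd_beta: float = 0.05
    nb_dispersion: float = 0.02
    confound_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_pairs_per_class, self.n_probes, self.n_genes) < 1:
            raise ValidationError("universe sizes must be >= 1")
        if self.n_planted_epidrivers < 0:
            raise ValidationError("n_planted_epidrivers must be >= 0")
        if not (0.0 < self.coupling_r < 1.0):
            raise ValidationError("coupling_r must lie in (0,1)")
        if not (0.0 < self.delta_beta_effect < 1.0):
            raise ValidationError("delta_beta_effect must lie in (0,1)")
        if not (0.0 <= self.confound_fraction <= 1.0):
            raise ValidationError("confound_fraction must lie in [0,1]")
        if self.noise_sd_beta <= 0 or self.nb_dispersion < 0:
            raise ValidationError("noise_sd_beta must be > 0 and nb_dispersion >= 0")
        if any(m < 0 for m in self.markers_per_class):
            raise ValidationError("marker counts must be >= 0")

    @property
    def markers_per_class(self) -> tuple[int, ...]:
        m = self.n_planted_markers_per_class
        if isinstance(m, int):
            return (m,) * self.n_classes
        m = tuple(int(x) for x in m)
        if len(m) != self.n_classes:
            raise ValidationError(
                f"n_planted_markers_per_class has {len(m)} entries for {self.n_classes} classes"
            )
        return m

    @property
    def n_markers(self) -> int:
        return sum(self.markers_per_class)


@dataclass
class GroundTruth:
    """Everything planted, for direct recomputation in tests."""

    planted_epidriver_genes: list[str]
    planted_marker_probes: dict[str, list[str]]  # class_label -> probes
    coupled_pairs: list[dict]  # probe_id, gene_id, region, sign
    confounded_genes: list[str]
    confounded_probes: dict[str, str]  # gene -> its shifted body probe
    high_missing_probes: list[str]
    regions: pd.DataFrame = field(repr=False, default=None)  # probe_id,gene_id,region,slot

    def to_json(self, path: Path) -> Path:
        payload = dataclasses.asdict(self)
        payload["regions"] = self.regions.to_dict(orient="records")
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["regions"] = pd.DataFrame(payload["regions"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# gene/probe universe
# ---------------------------------------------------------------------------


def _gene_plan(cfg: SimulationConfig) -> dict[str, list[str]]:
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    nd = cfg.n_planted_epidrivers
    need = nd * (1 + COMPANIONS_PER_DRIVER)
    if cfg.n_genes < need:
        raise ValidationError(
            f"n_genes={cfg.n_genes} cannot host {nd} drivers with "
            f"{COMPANIONS_PER_DRIVER} companions each (need >= {need})"
        )
    drivers = genes[:nd]
    companions = [
        genes[nd + i * COMPANIONS_PER_DRIVER : nd + (i + 1) * COMPANIONS_PER_DRIVER]
        for i in range(nd)
    ]
    background = genes[need:]
    return {"genes": genes, "drivers": drivers, "companions": companions, "background": background}


def generate_manifest_and_genes(
    cfg: SimulationConfig,
) -> tuple[ProbeManifest, GeneModel, pd.DataFrame]:
    """Lay out genes and probes with a known region assignment.

    Every gene gets one upstream (1-1500 bp 5' of TSS), one downstream
    (0-1500 bp 3' of TSS) and one gene-body probe; remaining probes alternate
    between intergenic positions on a gene-free chromosome and extra
    gene-body probes of the first genes (marker hosts).  Eight nuisance
    probes (chrX/chrY/SNP/multi-mapping) are always included.
    """
    min_probes = N_SPECIAL_PROBES + 3 * cfg.n_genes + 1
    if cfg.n_probes < min_probes:
        raise ValidationError(
            f"n_probes={cfg.n_probes} too small to cover all region categories "
            f"(need >= {min_probes} for {cfg.n_genes} genes)"
        )
    plan = _gene_plan(cfg)
    gene_rows = []
    for i, gid in enumerate(plan["genes"]):
        chrom = f"chr{(i % 4) + 1}"
        start = 100_000 + (i // 4) * 100_000
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, tes = start, start + 8_000
        else:
            tss, tes = start + 8_000, start
        gene_rows.append((gid, chrom, strand, tss, tes))
    genes = GeneModel(
        pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tes"]
        ).set_index("gene_id")
    )

    islands = list(("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"))
    rows = []  # probe_id, chrom, pos, island_relation, snp, multi, gene, region, slot
    pid = 0

    def add(chrom, pos, rel, snp, multi, gene, region, slot):
        nonlocal pid
        rows.append((f"cg{pid:06d}", chrom, int(pos), rel, snp, multi, gene, region, slot))
        pid += 1

    # nuisance probes on sex chromosomes / flagged probes (intergenic slots)
    add("chrX", 5_000, "Island", False, False, "", "igr", "special_x")
    add("chrX", 9_000, "OpenSea", False, False, "", "igr", "special_x")
    add("chrY", 5_000, "OpenSea", False, False, "", "igr", "special_y")
    add("chrY", 9_000, "N_Shore", False, False, "", "igr", "special_y")
    add("chr9", 1_000_000, "OpenSea", True, False, "", "igr", "special_snp")
    add("chr9", 1_005_000, "S_Shelf", True, False, "", "igr", "special_snp")
    add("chr9", 1_010_000, "OpenSea", False, True, "", "igr", "special_multi")
    add("chr9", 1_015_000, "Island", False, True, "", "igr", "special_multi")

    gt = genes.table
    for i, gid in enumerate(plan["genes"]):
        chrom, strand, tss = gt.loc[gid, "chrom"], gt.loc[gid, "strand"], gt.loc[gid, "tss"]
        up_off = 200 + (i * 97) % 1_300  # in [1, 1500]
        dn_off = (i * 89) % 1_400  # in [0, 1500]
        body_off = 1_501 + (i * 131) % 6_000  # beyond the downstream window, inside span
        sgn = 1 if strand == "+" else -1
        add(chrom, tss - sgn * up_off, "Island", False, False, gid, "upstream_1500", "upstream")
        add(chrom, tss + sgn * dn_off, islands[i % 3], False, False, gid, "downstream_1500", "downstream")
        add(chrom, tss + sgn * body_off, "OpenSea", False, False, gid, "gene_body", "body")

    # remaining probes: alternate intergenic (chr9, gene-free) and extra body
    # probes of the first genes, which host the planted markers
    n_hosts = max(1, min(12, cfg.n_genes))
    extra_i = 0
    while pid < cfg.n_probes:
        if extra_i % 2 == 0:
            add("chr9", 2_000_000 + extra_i * 5_000, islands[extra_i % 6], False, False, "", "igr", "igr")
        else:
            g_idx = (extra_i // 2) % n_hosts
            gid = plan["genes"][g_idx]
            chrom, strand, tss = gt.loc[gid, "chrom"], gt.loc[gid, "strand"], gt.loc[gid, "tss"]
            sgn = 1 if strand == "+" else -1
            body_off = 1_601 + ((extra_i // 2) // n_hosts) * 97 + (g_idx * 13) % 50
            add(chrom, tss + sgn * body_off, "OpenSea", False, False, gid, "gene_body", "extra_body")
        extra_i += 1

    df = pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "pos", "island_relation", "snp_flag",
                 "multimap_flag", "gene_id", "region", "slot"],
    )
    manifest = ProbeManifest(
        df.set_index("probe_id")[["chrom", "pos", "island_relation", "snp_flag", "multimap_flag"]]
    )
    truth_regions = df[["probe_id", "gene_id", "region", "slot"]].copy()
    for cat in ("upstream_1500", "downstream_1500", "gene_body", "igr"):
        if not (truth_regions["region"] == cat).any():  # pragma: no cover - guarded above
            raise ValidationError(f"generated universe lacks region category {cat}")
    return manifest, genes, truth_regions


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def generate_networks(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> tuple[ReactionTable, EdgeList]:
    """Reaction chains and PPI edges that make planted drivers upstream hubs.

    Metabolic design per driver d with companions c0..c10: d's product feeds
    c0..c3; c0 -> c4 -> c5 continues the chain; c0 and c4 are diluted with
    two background targets each, so chain enzymes are *not* module-enriched.
    Every background gene gets one companion target plus two background
    targets (finite but low/negative importance scores).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    plan = _gene_plan(cfg)
    drivers, companions, background = plan["drivers"], plan["companions"], plan["background"]
    rx = []  # (reaction_id, enzyme, substrates, products)
    rid = 0

    def reaction(enzyme, subs, prods):
        nonlocal rid
        rx.append((f"rx{rid:05d}", enzyme, ";".join(subs), ";".join(prods)))
        rid += 1

    def bg_pick(k):
        if len(background) == 0:
            return []
        idx = rng.choice(len(background), size=min(k, len(background)), replace=False)
        return [background[j] for j in idx]

    for i, d in enumerate(drivers):
        comp = companions[i]
        p = f"met_d{i}"  # driver product
        reaction(d, [f"sub_d{i}"], [p])
        for j in range(4):  # fan-out: all four targets inside the module
            prods = [f"met_c{i}_{j}"] if j == 0 else [f"dead_{i}_{j}"]
            reaction(comp[j], [p], prods)
        q = f"met_c{i}_0"  # c0's product -> c4 plus two background consumers
        reaction(comp[4], [q], [f"met_e{i}"])
        for b in bg_pick(2):
            reaction(b, [q], [f"dead_b{rid}"])
        r = f"met_e{i}"  # c4's product -> c5 plus two background consumers
        reaction(comp[5], [r], [f"dead_end_{i}"])
        for b in bg_pick(2):
            reaction(b, [r], [f"dead_b{rid}"])

    all_comp = [c for block in companions for c in block]
    for k, b in enumerate(background):
        mk = f"met_b{k}"
        reaction(b, [f"sub_b{k}"], [mk])
        if all_comp:
            c = all_comp[int(rng.integers(len(all_comp)))]
            reaction(c, [mk], [f"dead_c{rid}"])
        for b2 in bg_pick(2):
            if b2 != b:
                reaction(b2, [mk], [f"dead_b{rid}"])

    reactions = ReactionTable(
        pd.DataFrame(rx, columns=["reaction_id", "enzyme_gene", "substrates", "products"])
        .assign(
            substrates=lambda d: d["substrates"].map(lambda s: frozenset(s.split(";"))),
            products=lambda d: d["products"].map(lambda s: frozenset(s.split(";"))),
        )
        .set_index("reaction_id")
    )

    edges = []
    for i, d in enumerate(drivers):
        for c in companions[i]:
            edges.append((d, c, float(np.round(rng.uniform(0.5, 0.9), 6))))
    for k, b in enumerate(background):
        for b2 in bg_pick(2):
            if b2 != b:
                edges.append((b, b2, float(np.round(rng.uniform(0.1, 0.9), 6))))
        if all_comp:
            c = all_comp[int(rng.integers(len(all_comp)))]
            edges.append((b, c, float(np.round(rng.uniform(0.45, 0.9), 6))))
    if len(plan["genes"]) >= 2:  # guaranteed sub-threshold edge exercises the 0.4 cutoff
        edges.append((plan["genes"][-1], plan["genes"][-2], 0.2))
    ppi = EdgeList(pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]), directed=False)
    return reactions, ppi


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _beta_noise(mean: np.ndarray, rng: np.random.Generator, sd_beta: float) -> np.ndarray:
    """Additive noise on the logit scale, clipped to [0.001, 0.999]."""
    m = np.clip(mean, 0.001, 0.999)
    return expit(logit(m) + rng.normal(0.0, 4.0 * sd_beta, size=np.shape(m)))


def generate_cohort(
    cfg: SimulationConfig,
    manifest: ProbeManifest,
    genes: GeneModel,
    truth_regions: pd.DataFrame,
) -> tuple[BetaMatrix, CountMatrix, SampleSheet, GroundTruth]:
    rng = np.random.default_rng(cfg.seed + 2)
    plan = _gene_plan(cfg)
    classes = [f"class{k:02d}" for k in range(cfg.n_classes)]

    sample_rows = []
    for k, cl in enumerate(classes):
        for p in range(cfg.n_pairs_per_class):
            pair = f"{cl}_p{p:03d}"
            sample_rows.append((f"{cl}_T{p:03d}", cl, "tumor", pair, ""))
            sample_rows.append((f"{cl}_N{p:03d}", cl, "normal", pair, ""))
    samples = SampleSheet(
        pd.DataFrame(
            sample_rows, columns=["sample_id", "class_label", "condition", "pair_id", "cohort"]
        ).set_index("sample_id")
    )
    sam = samples.table
    sample_ids = list(sam.index)
    tumor_mask = (sam["condition"] == "tumor").to_numpy()
    class_of = sam["class_label"].to_numpy()
    n_s = len(sample_ids)

    by_slot = truth_regions.set_index(["gene_id", "slot"]).sort_index()
    def probes_of(gene: str, slot: str) -> list[str]:
        try:
            sel = by_slot.loc[(gene, slot), "probe_id"]
        except KeyError:
            return []
        return [sel] if isinstance(sel, str) else list(sel)

    # ---- marker plan -----------------------------------------------------
    marker_classes: list[str] = []
    for cl, n_m in zip(classes, cfg.markers_per_class):
        marker_classes.extend([cl] * n_m)
    hosts_pool = plan["drivers"] if plan["drivers"] else plan["genes"][:5]
    host_cycle = hosts_pool[: min(5, len(hosts_pool))]
    marker_probes: list[str] = []
    used: dict[str, int] = {}
    for m_idx in range(len(marker_classes)):
        host = host_cycle[m_idx % len(host_cycle)]
        extras = probes_of(host, "extra_body")
        j = used.get(host, 0)
        if j >= len(extras):
            raise ValidationError(
                f"not enough extra gene-body probes on marker host {host!r}; "
                f"increase n_probes"
            )
        marker_probes.append(extras[j])
        used[host] = j + 1

    # ---- confounded genes ------------------------------------------------
    n_conf = int(round(cfg.confound_fraction * cfg.n_genes))
    confounded = plan["background"][: min(n_conf, len(plan["background"]))]

    # ---- expression + beta (retry loop for the coupling target) ----------
    sd_count_est = np.sqrt(cfg.nb_dispersion + 0.01) / np.log(2.0)
    r_max = MODULE_LOADING / np.sqrt(MODULE_LOADING**2 + EXPR_NOISE_SD**2 + sd_count_est**2)
    loading_a = min(0.995, cfg.coupling_r * 1.06 / r_max)

    base = rng.uniform(3.0, 8.0, size=cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(plan["genes"])}
    for d in plan["drivers"]:
        base[gene_pos[d]] = rng.uniform(6.0, 8.0)
    for block in plan["companions"]:
        for c in block:
            base[gene_pos[c]] = rng.uniform(6.5, 8.0)
    # background genes carry most of the library mass (ballast), so no single
    # module dominates the CPM denominator and compositionally couples the rest
    for g in plan["background"]:
        base[gene_pos[g]] = rng.uniform(8.0, 11.0)
    scale = rng.uniform(0.8, 1.25, size=n_s)
    module_sign = np.array([1.0 if i % 2 == 0 else -1.0
                            for i in range(len(plan["drivers"]))])

    u_class = {}  # confounded gene -> per-class shift in [-1, 1]
    grid = np.linspace(-1.0, 1.0, cfg.n_classes) if cfg.n_classes > 1 else np.array([1.0])
    for g in confounded:
        u_class[g] = dict(zip(classes, rng.permutation(grid)))

    baseline_beta = rng.uniform(0.1, 0.9, size=cfg.n_probes)
    probe_ids = list(truth_regions["probe_id"])
    probe_pos = {p: i for i, p in enumerate(probe_ids)}

    last_err = ""
    for attempt in range(6):
        sub = np.random.default_rng(rng.integers(2**31))
        log_expr = base[:, None] + sub.normal(0.0, EXPR_NOISE_SD, size=(cfg.n_genes, n_s))
        beta_mean = np.repeat(baseline_beta[:, None], n_s, axis=1)

        coupled_pairs = []
        for i, d in enumerate(plan["drivers"]):
            gi = gene_pos[d]
            u = sub.uniform(0.15, 0.85, size=int(tumor_mask.sum()))
            u_std = (u - 0.5) / (0.7 / np.sqrt(12.0))
            f = loading_a * u_std + np.sqrt(max(0.0, 1 - loading_a**2)) * sub.normal(size=u.size)
            log_expr[gi, tumor_mask] += MODULE_LOADING * f
            for c in plan["companions"][i]:
                log_expr[gene_pos[c], tumor_mask] += (
                    module_sign[i] * COMPANION_LOG2FC + MODULE_LOADING * f
                )
            body = probes_of(d, "body")[0]
            prom = probes_of(d, "upstream")[0]
            down = probes_of(d, "downstream")[0]
            beta_mean[probe_pos[body], tumor_mask] = u
            beta_mean[probe_pos[body], ~tumor_mask] = 0.5 - cfg.delta_beta_effect
            beta_mean[probe_pos[prom], tumor_mask] = 1.0 - u
            beta_mean[probe_pos[prom], ~tumor_mask] = 0.5 + cfg.delta_beta_effect
            # a second positively coupled probe keeps the gene's window-mean
            # methylation informative (the +/- pair alone would cancel in it)
            beta_mean[probe_pos[down], tumor_mask] = u
            beta_mean[probe_pos[down], ~tumor_mask] = 0.5 - cfg.delta_beta_effect
            coupled_pairs.append({"probe_id": body, "gene_id": d, "region": "gene_body", "sign": "+"})
            coupled_pairs.append({"probe_id": prom, "gene_id": d, "region": "upstream_1500", "sign": "-"})
            coupled_pairs.append({"probe_id": down, "gene_id": d, "region": "downstream_1500", "sign": "+"})

        for g in confounded:
            gi = gene_pos[g]
            shift = np.array([u_class[g][c] for c in class_of])
            log_expr[gi, tumor_mask] += CONFOUND_EXPR_SCALE * shift[tumor_mask]
            probe = probes_of(g, "body")[0]
            beta_mean[probe_pos[probe]] = 0.5 + CONFOUND_BETA_SCALE * shift

        # planted drivers must shift by DRIVER_LOG2FC on the *CPM* scale, so the
        # raw shift is inflated by the tumor/normal library-composition ratio
        # (companions and drivers change the library total); solved by fixed point
        if plan["drivers"]:
            drv_rows = np.array([gene_pos[d] for d in plan["drivers"]])
            drv_sign = module_sign[: len(drv_rows)]
            tot = np.power(2.0, log_expr).sum(axis=0)
            drv_mass = np.power(2.0, log_expr[drv_rows])
            infl = 0.0
            for _ in range(4):
                shifts = drv_sign * DRIVER_LOG2FC + infl
                tot_adj = tot.copy()
                tot_adj[tumor_mask] += (
                    drv_mass[:, tumor_mask] * (np.power(2.0, shifts)[:, None] - 1.0)
                ).sum(axis=0)
                infl = float(np.mean(np.log2(tot_adj[tumor_mask])) - np.mean(np.log2(tot_adj[~tumor_mask])))
            log_expr[np.ix_(drv_rows, tumor_mask)] += (
                drv_sign * DRIVER_LOG2FC + infl
            )[:, None]

        beta_vals = _beta_noise(beta_mean, sub, cfg.noise_sd_beta)

        # marker probes: tight high beta (rest mean + separation) in the
        # marked class's tumors; everywhere else a bimodal mixture whose
        # distribution is identical across the unmarked classes, so a marker
        # probe carries information about its own class only
        lo_mode, hi_mode = MARKER_REST_MODES
        rest_mean = 0.5 * (lo_mode + hi_mode)
        for probe, cl in zip(marker_probes, marker_classes):
            marked = tumor_mask & (class_of == cl)
            modes = np.where(sub.random(n_s) < 0.5, lo_mode, hi_mode)
            row = expit(logit(modes) + sub.normal(0.0, 4.0 * MARKER_MODE_SD, size=n_s))
            high = np.clip(rest_mean + cfg.marker_separation, 0.001, 0.999)
            row[marked] = expit(
                logit(high) + sub.normal(0.0, 4.0 * cfg.noise_sd_beta, size=int(marked.sum()))
            )
            beta_vals[probe_pos[probe]] = row

        mu = np.power(2.0, log_expr) * scale[None, :]
        if cfg.nb_dispersion > 0:
            lam = sub.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
        else:
            lam = mu
        counts_vals = sub.poisson(lam).astype(np.int64)

        # verify that the emitted matrices actually carry the coupling
        with np.errstate(invalid="ignore"):
            cpm = counts_vals / counts_vals.sum(axis=0, keepdims=True) * 1e6
        log_cpm = np.log2(cpm + 1.0)
        ok = True
        for pair in coupled_pairs:
            x = beta_vals[probe_pos[pair["probe_id"]], tumor_mask]
            y = log_cpm[gene_pos[pair["gene_id"]], tumor_mask]
            r = np.corrcoef(x, y)[0, 1]
            if abs(r) < cfg.coupling_r - 0.1 or np.sign(r) != (1 if pair["sign"] == "+" else -1):
                ok = False
                last_err = f"pair {pair['probe_id']}/{pair['gene_id']}: |r|={abs(r):.3f}"
                break
        if ok:
            break
        loading_a = min(0.995, loading_a + 0.05)
    else:
        raise ValidationError(
            f"infeasible config: could not reach |r| >= coupling_r - 0.1 "
            f"after bounded retries ({last_err})"
        )

    # ---- missingness -----------------------------------------------------
    protected = set(marker_probes) | {p["probe_id"] for p in coupled_pairs}
    protected |= {probes_of(g, "body")[0] for g in confounded}
    free_idx = np.array([i for i, p in enumerate(probe_ids) if p not in protected])
    miss = np.zeros_like(beta_vals, dtype=bool)
    if free_idx.size:
        m = rng.random((free_idx.size, n_s)) < 0.02
        miss[free_idx] = m
    igr_free = [p for p in probe_ids if p not in protected and truth_regions.set_index("probe_id").loc[p, "slot"] == "igr"]
    high_missing = igr_free[:3]
    for p in high_missing:
        cols = rng.choice(n_s, size=int(np.ceil(0.6 * n_s)), replace=False)
        miss[probe_pos[p], cols] = True
    beta_vals = beta_vals.copy()
    beta_vals[miss] = np.nan

    beta = BetaMatrix(pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids))
    counts = CountMatrix(pd.DataFrame(counts_vals, index=plan["genes"], columns=sample_ids))

    marker_map: dict[str, list[str]] = {cl: [] for cl in classes}
    for probe, cl in zip(marker_probes, marker_classes):
        marker_map[cl].append(probe)
    truth = GroundTruth(
        planted_epidriver_genes=list(plan["drivers"]),
        planted_marker_probes=marker_map,
        coupled_pairs=coupled_pairs,
        confounded_genes=list(confounded),
        confounded_probes={g: probes_of(g, "body")[0] for g in confounded},
        high_missing_probes=list(high_missing),
        regions=truth_regions,
    )
    return beta, counts, samples, truth


def generate_bundle(cfg: SimulationConfig) -> tuple[Bundle, GroundTruth]:
    """Full deterministic bundle + ground truth for a configuration."""
    manifest, genes, truth_regions = generate_manifest_and_genes(cfg)
    reactions, ppi = generate_networks(cfg)
    beta, counts, samples, truth = generate_cohort(cfg, manifest, genes, truth_regions)
    bundle = Bundle(beta, counts, manifest, genes, samples, reactions, ppi, BundleReport())
    return bundle, truth
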