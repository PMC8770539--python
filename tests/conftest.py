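import numpy as np
import pandas as pd
import pytest

import epiorigin as eo

# a small but fully structured cohort: 3 tissue classes, 4 planted drivers
# with companion modules, 3 planted markers, confounding and missingness
SMALL = dict(
    n_classes=3,
    n_pairs_per_class=15,
    n_probes=340,
    n_genes=100,
    n_planted_epidrivers=4,
    n_planted_markers_per_class=(1, 1, 1),
    seed=7,
)


@pytest.fixture(scope="session")
def small_cfg() -> eo.SimulationConfig:
    return eo.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return eo.generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def qc_beta(small_bundle):
    bundle, _ = small_bundle
    beta, report = eo.qc(bundle.beta, bundle.manifest)
    return beta, report


def make_beta(values, probes=None, samples=None) -> eo.BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i:02d}" for i in range(arr.shape[1])]
    return eo.BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


def make_samples(conditions, classes=None, pairs=None, cohort=None) -> eo.SampleSheet:
    n = len(conditions)
    ids = [f"s{i:02d}" for i in range(n)]
    return eo.SampleSheet(pd.DataFrame({
        "class_label": classes or ["A"] * n,
        "condition": conditions,
        "pair_id": pairs or [""] * n,
        "cohort": cohort or [""] * n,
    }, index=pd.Index(ids, name="sample_id")))


def make_manifest(rows) -> eo.ProbeManifest:
    """rows: (probe_id, chrom, pos, island, snp, multi)."""
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "island_relation",
                                     "snp_flag", "multimap_flag"]).set_index("probe_id")
    return eo.ProbeManifest(df)
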