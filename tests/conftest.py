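import json
from pathlib import Path

import numpy as np
import pytest

from hydroxymet.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default synthetic cohort (300 genes, 5 Mb, 17 pairs), simulated
    once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(seed=7)
    paths = simulate_cohort(cfg, outdir)
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    return {"config": cfg, "paths": paths, "truth": truth, "dir": Path(outdir)}


@pytest.fixture(scope="session")
def small_config():
    """A miniature cohort configuration for fast structural tests."""
    return SimConfig(
        seed=5,
        n_genes=40,
        chrom_length=1_000_000,
        n_reads_ip=20_000,
        n_reads_input=20_000,
        n_dip_normals=2,
        n_dip_tumours=2,
        n_pairs=4,
        probes_per_gene=4,
        edge_margin=15_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
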