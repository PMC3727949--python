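from __future__ import annotations

import numpy as np
import pytest

from bgscan.io import PopulationPanel
from bgscan.sites import CONS_CODE, SiteTable
from bgscan.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture
def panel4() -> PopulationPanel:
    """Two populations of two samples each."""
    return PopulationPanel.from_mapping(
        {"A1": "POPA", "A2": "POPA", "B1": "POPB", "B2": "POPB"}
    )


def build_table(rows, panel) -> SiteTable:
    """Build a SiteTable from compact per-site tuples.

    Each row: (chrom, pos0, genotypes, gerp, consequence, ancestral);
    ref/alt fixed to A/G.
    """
    n = len(rows)
    chrom = np.array([r[0] for r in rows], dtype=object)
    pos0 = np.array([r[1] for r in rows], dtype=np.int64)
    geno = np.array([r[2] for r in rows], dtype=np.int8).reshape(n, -1)
    gerp = np.array(
        [np.nan if r[3] is None else r[3] for r in rows], dtype=float
    )
    cons = np.array([CONS_CODE[r[4]] for r in rows], dtype=np.int8)
    anc = np.array([r[5] for r in rows], dtype=object)
    ref = np.array(["A"] * n, dtype=object)
    alt = np.array(["G"] * n, dtype=object)
    return SiteTable(chrom, pos0, ref, alt, geno, gerp, cons, anc, panel)


@pytest.fixture
def make_table(panel4):
    def _make(rows, panel=None):
        return build_table(rows, panel or panel4)

    return _make


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_genes=12)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    """Small full-featured dataset (genes, elements, strips, 3 populations)."""
    return simulate_dataset(small_cfg, seed=5)


@pytest.fixture(scope="session")
def dataset_dir(small_ds, tmp_path_factory):
    """The small dataset written to disk in all on-disk formats."""
    outdir = tmp_path_factory.mktemp("dataset")
    write_dataset(small_ds, outdir)
    return outdir
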