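import numpy as np
import pandas as pd
import pytest

from seqspace import cellgrid as cg
from seqspace import codebook as cbm
from seqspace import synthdata as sd


@pytest.fixture(scope="session")
def small_config():
    """A compact paired simulation: 3 types, 30-gene panel, one embryo."""
    return sd.SimConfig(
        n_genes_total=200,
        n_genes_panel=30,
        n_ref_cells=600,
        n_embryos=1,
        n_z_slices=2,
        fovs_per_embryo=1,
        cells_per_fov=100,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return sd.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_section(small_config, small_reference):
    return sd.generate_section(small_config, small_reference)


@pytest.fixture(scope="session")
def small_codebook(small_section):
    _, truth = small_section
    return cbm.build_codebook(truth.panel, seed=42)


@pytest.fixture(scope="session")
def quantified(small_config, small_reference, small_section):
    """True molecules assigned to cells, QC-filtered and normalized."""
    cells, truth = small_section
    counts = cg.assign_spots(truth.molecules, cells, genes=truth.panel)
    cells_f, counts_f = cg.qc_filter(cells, counts)
    normed = cg.normalize(counts_f)
    return cells_f, normed, truth


@pytest.fixture(scope="session")
def paired_lognorm(small_reference, quantified):
    """Aligned (spatial lognorm, reference lognorm, batches, meta) tables."""
    cells_f, normed, truth = quantified
    sp_log = pd.DataFrame(
        normed.layers["lognorm"], index=normed.obs_names, columns=normed.var_names
    )
    ref_log = pd.DataFrame(
        small_reference.layers["lognorm"],
        index=small_reference.obs_names,
        columns=small_reference.var_names,
    )[truth.panel]
    sp_batches = (
        normed.obs["embryo"].astype(str) + "/z" + normed.obs["z_slice"].astype(str)
    ).to_numpy()
    meta = truth.cells.loc[[int(i) for i in normed.obs_names]]
    return sp_log, ref_log, sp_batches, small_reference.obs["batch"].to_numpy(), meta
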