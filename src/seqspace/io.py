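"""Readers and writers for the pipeline's on-disk formats.

Spots travel as delimited tables, polygons as GeoJSON, matrices as
MatrixMarket plus row/column annotation tables, configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .synthdata import SimConfig

__all__ = [
    "write_spots",
    "read_spots",
    "write_counts",
    "read_counts",
    "write_config",
    "read_config",
]


def write_spots(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spots(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(adata: ad.AnnData, prefix) -> None:
    """Write an AnnData as <prefix>.mtx / <prefix>.obs.tsv / <prefix>.var.tsv."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(np.asarray(adata.X)))
    adata.obs.to_csv(prefix.with_suffix(".obs.tsv"), sep="\t")
    adata.var.to_csv(prefix.with_suffix(".var.tsv"), sep="\t")


def read_counts(prefix) -> ad.AnnData:
    prefix = Path(prefix)
    X = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    obs = pd.read_csv(prefix.with_suffix(".obs.tsv"), sep="\t", index_col=0)
    var = pd.read_csv(prefix.with_suffix(".var.tsv"), sep="\t", index_col=0)
    obs.index = obs.index.map(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig(**yaml.safe_load(fh))
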