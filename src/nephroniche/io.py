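"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices go to MatrixMarket (.mtx) plus genes.tsv/barcodes.tsv; bead,
spot, and 3D cell tables are CSV with coordinates in µm; ground truth and
marker sets are JSON; gene sets are one gene symbol per line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as spio
from scipy import sparse


def write_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write genes x cells MTX with genes.tsv, barcodes.tsv, metadata.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    spio.mmwrite(outdir / "matrix.mtx", x.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.csv")


def read_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    x = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    meta = indir / "metadata.csv"
    if meta.exists():
        obs = pd.read_csv(meta, index_col=0)
    return ad.AnnData(X=x, obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth(truth, path: str | Path) -> None:
    """Serialize a ground-truth dataclass (or dict) to JSON."""
    obj = dataclasses.asdict(truth) if dataclasses.is_dataclass(truth) else truth
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def read_gene_set(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
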