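"""Readers and writers for the on-disk formats the pipeline uses.

Expression data travel as a 10x-style directory (``matrix.mtx`` genes x
cells, ``features.tsv``, ``barcodes.tsv``) plus a cell-metadata TSV; gene
sets as GMT; ligand-receptor databases as three-column TSV; vessel images
as multichannel TIFF with a sidecar JSON mapping channel roles.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
from anndata import AnnData


def write_expression_dir(adata: AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = sp.csr_matrix(adata.X).T.astype(int)  # genes x cells, 10x dialect
    scipy.io.mmwrite(outdir / "matrix.mtx", m)
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": adata.obs_names}).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_expression_dir(indir) -> AnnData:
    indir = Path(indir)
    m = scipy.io.mmread(indir / "matrix.mtx").tocsr().T  # cells x genes
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mt"] = [str(g).upper().startswith("MT-") for g in genes]
    return AnnData(X=np.asarray(m.todense(), dtype=np.int32), obs=obs, var=var)


def read_csv_matrix(path) -> AnnData:
    """Dense genes-as-rows CSV -> AnnData (cells x genes)."""
    df = pd.read_csv(path, index_col=0)
    var = pd.DataFrame(index=pd.Index(df.index, name="gene"))
    var["mt"] = [str(g).upper().startswith("MT-") for g in df.index]
    return AnnData(X=df.to_numpy().T, obs=pd.DataFrame(index=df.columns), var=var)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def read_lr_database(path) -> pd.DataFrame:
    db = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor", "weight"}
    if not required <= set(db.columns):
        raise ValueError(f"LR database must have columns {sorted(required)}")
    if ((db["weight"] < 0) | (db["weight"] > 1)).any():
        raise ValueError("pair weights must lie in [0, 1]")
    return db


def write_image(img: np.ndarray, roles: list[str], path, truth=None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    sidecar = {"channels": list(roles)}
    if truth is not None:
        sidecar["truth"] = truth
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_image(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    img = tifffile.imread(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return img, sidecar["channels"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None, index=False) -> None:
    """TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
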