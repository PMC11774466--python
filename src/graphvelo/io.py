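"""Reading and writing datasets in h5ad, MatrixMarket+TSV, and CSV form.

The h5ad dialect follows the anndata conventions used across the single-cell
ecosystem: expression in ``X`` or a named layer, velocities in a layer
(``velocity`` or ``velocity_S``), low-dimensional coordinates under ``obsm``
keys such as ``X_pca``, and the neighbor graph under ``obsp`` sparse
distance/connectivity matrices.  MatrixMarket datasets are a directory with
``matrix.mtx``, ``features.tsv`` and ``cells.tsv`` (optionally
``velocity.mtx``); CSV files carry a header row of feature ids and a first
column of cell ids (optionally a ``<stem>.velocity.csv`` sidecar).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import CellStateSet, NeighborGraph, VelocityField

__all__ = ["NamedKeyError", "read_dataset", "write_dataset"]

_VELOCITY_KEYS = ("velocity", "velocity_S")


class NamedKeyError(KeyError):
    """A requested layer/obsm/obsp key is absent; lists what is available."""

    def __init__(self, kind: str, key: str, available) -> None:
        super().__init__(
            f"{kind} key {key!r} not found; available: {sorted(available)}"
        )


def _graph_from_distance_matrix(dist) -> NeighborGraph | None:
    """Rebuild a NeighborGraph from a sparse obsp distance matrix."""
    import scipy.sparse as sp

    dist = sp.csr_matrix(dist)
    n = dist.shape[0]
    counts = np.diff(dist.indptr)
    if counts.min() == 0 or counts.min() != counts.max():
        return None  # not a uniform kNN graph
    k = int(counts[0])
    idx = dist.indices.reshape(n, k)
    d = dist.data.reshape(n, k)
    order = np.argsort(d, axis=1, kind="stable")
    return NeighborGraph(
        k=k,
        indices=np.take_along_axis(idx, order, axis=1),
        distances=np.take_along_axis(d, order, axis=1),
    )


def read_dataset(path: str, format: str = "h5ad", *, layer: str | None = None,
                 velocity_key: str | None = None, rep: str | None = None):
    """Load (states, velocity-or-None, graph-or-None) from disk.

    ``rep`` selects an obsm embedding instead of the main matrix for h5ad
    input.  Round-trips with :func:`write_dataset` preserve values bit-for-bit
    and names exactly.
    """
    if format in ("h5ad", "h5ad-dialect"):
        return _read_h5ad(path, layer=layer, velocity_key=velocity_key, rep=rep)
    if format == "mtx":
        return _read_mtx(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}; use h5ad, mtx, or csv")


def _read_h5ad(path, *, layer=None, velocity_key=None, rep=None):
    import anndata as ad

    adata = ad.read_h5ad(path)
    if rep is not None and rep not in ("genes", "X"):
        if rep not in adata.obsm:
            raise NamedKeyError("obsm", rep, adata.obsm.keys())
        values = np.asarray(adata.obsm[rep])
        feature_ids = [f"{rep}_{i}" for i in range(values.shape[1])]
        representation = rep
    elif layer is not None:
        if layer not in adata.layers:
            raise NamedKeyError("layer", layer, adata.layers.keys())
        values = adata.layers[layer]
        feature_ids = list(adata.var_names)
        representation = "genes"
    else:
        values = adata.X
        feature_ids = list(adata.var_names)
        representation = "genes"
    states = CellStateSet(values, feature_ids, list(adata.obs_names),
                          representation=representation)

    vel = None
    if velocity_key is None:
        velocity_key = next((k for k in _VELOCITY_KEYS if k in adata.layers), None)
    elif velocity_key not in adata.layers:
        raise NamedKeyError("layer", velocity_key, adata.layers.keys())
    if velocity_key is not None and rep in (None, "genes", "X"):
        vel = VelocityField(adata.layers[velocity_key],
                            paired_representation=representation)

    graph = None
    if "distances" in adata.obsp:
        graph = _graph_from_distance_matrix(adata.obsp["distances"])
    return states, vel, graph


def _read_mtx(path):
    import scipy.io as sio

    mat = np.asarray(sio.mmread(os.path.join(path, "matrix.mtx")).todense()) \
        if _is_sparse_mtx(os.path.join(path, "matrix.mtx")) \
        else np.asarray(sio.mmread(os.path.join(path, "matrix.mtx")))
    features = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t",
                           header=None)[0].astype(str).tolist()
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t",
                        header=None)[0].astype(str).tolist()
    states = CellStateSet(mat, features, cells)
    vel = None
    vpath = os.path.join(path, "velocity.mtx")
    if os.path.exists(vpath):
        v = sio.mmread(vpath)
        v = np.asarray(v.todense()) if hasattr(v, "todense") else np.asarray(v)
        vel = VelocityField(v)
    return states, vel, None


def _is_sparse_mtx(path) -> bool:
    with open(path) as fh:
        return "coordinate" in fh.readline()


def _read_csv(path):
    # round_trip parser: the default fast float parser loses ulps
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    states = CellStateSet(df.to_numpy(dtype=float),
                          [str(c) for c in df.columns],
                          [str(i) for i in df.index])
    vel = None
    stem, _ = os.path.splitext(path)
    vpath = stem + ".velocity.csv"
    if os.path.exists(vpath):
        vdf = pd.read_csv(vpath, index_col=0, float_precision="round_trip")
        vel = VelocityField(vdf.to_numpy(dtype=float))
    return states, vel, None


def write_dataset(path: str, states: CellStateSet,
                  vel: VelocityField | None = None,
                  graph: NeighborGraph | None = None,
                  format: str = "h5ad", obsm: dict | None = None,
                  **extra_layers):
    """Write a dataset; inverse of :func:`read_dataset` for each format."""
    if format in ("h5ad", "h5ad-dialect"):
        _write_h5ad(path, states, vel, graph, obsm=obsm, **extra_layers)
    elif format == "mtx":
        _write_mtx(path, states, vel)
    elif format == "csv":
        _write_csv(path, states, vel)
    else:
        raise ValueError(f"unknown format {format!r}; use h5ad, mtx, or csv")


def _write_h5ad(path, states, vel, graph, obsm=None, **extra_layers):
    import anndata as ad
    import scipy.sparse as sp

    adata = ad.AnnData(
        X=states.values.copy(),
        obs=pd.DataFrame(index=pd.Index(states.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(states.feature_ids, name="feature_id")),
    )
    if vel is not None:
        adata.layers["velocity"] = vel.values.copy()
    for key, mat in extra_layers.items():
        adata.layers[key] = np.asarray(mat, dtype=float)
    for key, mat in (obsm or {}).items():
        adata.obsm[key] = np.asarray(mat, dtype=float)
    if graph is not None:
        n, k = graph.n_cells, graph.k
        rows = np.repeat(np.arange(n), k)
        dmat = sp.csr_matrix(
            (graph.distances.ravel(), (rows, graph.indices.ravel())),
            shape=(n, n),
        )
        adata.obsp["distances"] = dmat
        adata.uns["neighbors"] = {
            "params": {"n_neighbors": k, "metric": graph.metric,
                       "built_on": graph.built_on}
        }
    adata.write_h5ad(path)


def _write_mtx(path, states, vel):
    import scipy.io as sio

    os.makedirs(path, exist_ok=True)
    sio.mmwrite(os.path.join(path, "matrix.mtx"), np.asarray(states.values))
    pd.Series(states.feature_ids).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", index=False, header=False)
    pd.Series(states.cell_ids).to_csv(
        os.path.join(path, "cells.tsv"), sep="\t", index=False, header=False)
    if vel is not None:
        sio.mmwrite(os.path.join(path, "velocity.mtx"), np.asarray(vel.values))


def _write_csv(path, states, vel):
    pd.DataFrame(states.values, index=states.cell_ids,
                 columns=states.feature_ids).to_csv(path)
    if vel is not None:
        stem, _ = os.path.splitext(path)
        pd.DataFrame(vel.values, index=states.cell_ids,
                     columns=states.feature_ids).to_csv(stem + ".velocity.csv")
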