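"""Annotated cell-by-feature container and I/O.

:class:`CellPopulation` is a validated, lightweight container for a cell x
feature expression (or accessibility) matrix together with named layers
(spliced / unspliced / velocity), per-cell and per-feature annotations,
low-dimensional embeddings, and an optional neighbor graph.  It converts
to and from :class:`anndata.AnnData`, which backs the on-disk h5ad format;
a plain delimited-bundle format (directory of CSV files) is supported for
interoperability with non-Python tooling.

Missing velocity entries — features for which no upstream estimator produced
a velocity — are encoded as NaN in the ``"velocity"`` layer and masked by all
downstream operations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import NeighborGraph

__all__ = ["CellPopulation", "load_population", "save_population"]

# matrices with more entries than this are kept sparse if they arrive sparse
DENSE_ENTRY_LIMIT = 10_000_000


def _as_2d(mat) -> np.ndarray:
    """Dense float64 view of a matrix that may be scipy-sparse."""
    if sp.issparse(mat):
        return np.asarray(mat.todense(), dtype=np.float64)
    return np.asarray(mat, dtype=np.float64)


@dataclass
class CellPopulation:
    """Cell x feature state matrix with layers, annotations and embeddings.

    Parameters
    ----------
    X
        cells x features matrix of expression / accessibility values.
    layers
        Named matrices with the same shape as ``X`` (``"spliced"``,
        ``"unspliced"``, ``"velocity"``, ``"velocity_graphvelo"``, ...).
        The ``"velocity"`` layer may contain NaN only for features whose
        ``var["velocity_gene"]`` flag is False.
    obs, var
        Per-cell / per-feature annotation tables (category labels,
        pseudotime, viral_fraction; modality tags, velocity_gene flags,
        mack scores).
    obsm
        Named embeddings, ``n_cells`` rows each (``"pca"``, ``"spatial"``).
    graph
        Optional :class:`~graphvelo.graph.NeighborGraph`.
    """

    X: np.ndarray
    layers: Dict[str, np.ndarray] = field(default_factory=dict)
    obs: Optional[pd.DataFrame] = None
    var: Optional[pd.DataFrame] = None
    obsm: Dict[str, np.ndarray] = field(default_factory=dict)
    graph: Optional[NeighborGraph] = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.X):
            self.X = np.asarray(self.X, dtype=np.float64)
        self.layers = {
            k: (v if sp.issparse(v) else np.asarray(v, dtype=np.float64))
            for k, v in self.layers.items()
        }
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.RangeIndex(self.n_cells).astype(str))
        if self.var is None:
            self.var = pd.DataFrame(index=pd.RangeIndex(self.n_features).astype(str))
        self.obsm = {k: np.asarray(v, dtype=np.float64) for k, v in self.obsm.items()}
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def dense_X(self) -> np.ndarray:
        return _as_2d(self.X)

    def dense_layer(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"layer {name!r} not present")
        return _as_2d(self.layers[name])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d")
        if not np.all(np.isfinite(_as_2d(self.X))):
            raise ValueError("X contains non-finite values")
        for name, layer in self.layers.items():
            if layer.shape != self.X.shape:
                raise ValueError(
                    f"layer {name!r} has shape {layer.shape}, expected {self.X.shape}"
                )
            dense = _as_2d(layer)
            if "velocity" in name:
                # NaN marks features with no velocity estimate; inf never valid
                if np.any(np.isinf(dense)):
                    raise ValueError(f"layer {name!r} contains infinities")
                if name == "velocity" and "velocity_gene" in self.var.columns:
                    vg = np.asarray(self.var["velocity_gene"], dtype=bool)
                    if np.any(~np.isfinite(dense) & vg[None, :]):
                        raise ValueError(
                            "layer 'velocity' has missing values on velocity genes"
                        )
            elif not np.all(np.isfinite(dense)):
                raise ValueError(f"layer {name!r} contains non-finite values")
        if len(self.obs) != self.n_cells:
            raise ValueError("obs row count must equal n_cells")
        if len(self.var) != self.n_features:
            raise ValueError("var row count must equal n_features")
        for name, emb in self.obsm.items():
            if emb.shape[0] != self.n_cells:
                raise ValueError(
                    f"embedding {name!r} has {emb.shape[0]} rows, expected {self.n_cells}"
                )
        if self.graph is not None and self.graph.n_cells != self.n_cells:
            raise ValueError("neighbor graph cell count mismatch")

    # -- AnnData bridge --------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.X.copy() if not sp.issparse(self.X) else self.X.copy(),
            obs=self.obs.copy(),
            var=self.var.copy(),
        )
        for name, layer in self.layers.items():
            adata.layers[name] = layer.copy()
        for name, emb in self.obsm.items():
            adata.obsm[name] = emb.copy()
        if self.graph is not None and not self.graph.is_ragged:
            idx, dist = self.graph.as_arrays()
            adata.obsm["neighbor_indices"] = idx
            adata.obsm["neighbor_distances"] = dist
            adata.uns["neighbor_source"] = self.graph.source
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CellPopulation":
        graph = None
        obsm = {
            k: np.asarray(v)
            for k, v in adata.obsm.items()
            if k not in ("neighbor_indices", "neighbor_distances")
        }
        if "neighbor_indices" in adata.obsm:
            graph = NeighborGraph.from_arrays(
                np.asarray(adata.obsm["neighbor_indices"], dtype=np.int64),
                np.asarray(adata.obsm["neighbor_distances"], dtype=np.float64),
                source=str(adata.uns.get("neighbor_source", "external-wnn")),
            )
        X = adata.X
        if sp.issparse(X) and X.shape[0] * X.shape[1] <= DENSE_ENTRY_LIMIT:
            X = _as_2d(X)
        layers = {}
        for k in adata.layers.keys():
            lyr = adata.layers[k]
            layers[k] = _as_2d(lyr) if sp.issparse(lyr) and lyr.shape[0] * lyr.shape[1] <= DENSE_ENTRY_LIMIT else lyr
        return cls(
            X=X,
            layers=layers,
            obs=adata.obs.copy(),
            var=adata.var.copy(),
            obsm=obsm,
            graph=graph,
        )


def save_population(pop: CellPopulation, path, format: str = "h5ad") -> None:
    """Write a population to disk as h5ad or as a delimited CSV bundle."""
    pop.validate()
    path = Path(path)
    if format == "h5ad":
        pop.to_anndata().write_h5ad(path)
    elif format == "delimited-bundle":
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "X.csv", pop.dense_X(), delimiter=",", header=",".join(pop.var.index), comments="")
        for name, layer in pop.layers.items():
            np.savetxt(path / f"layer_{name}.csv", _as_2d(layer), delimiter=",",
                       header=",".join(pop.var.index), comments="")
        pop.obs.to_csv(path / "obs.csv")
        pop.var.to_csv(path / "var.csv")
        for name, emb in pop.obsm.items():
            np.savetxt(path / f"obsm_{name}.csv", emb, delimiter=",")
        if pop.graph is not None and not pop.graph.is_ragged:
            idx, dist = pop.graph.as_arrays()
            np.savetxt(path / "neighbor_indices.csv", idx, fmt="%d", delimiter=",")
            np.savetxt(path / "neighbor_distances.csv", dist, delimiter=",")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_population(path, format: str = "h5ad") -> CellPopulation:
    """Load a population written by :func:`save_population`.

    Raises a validation error (naming the offending layer) on shape
    mismatches and an OSError for unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file or directory: {path}")
    if format == "h5ad":
        import anndata as ad

        return CellPopulation.from_anndata(ad.read_h5ad(path))
    if format == "delimited-bundle":
        X = np.loadtxt(path / "X.csv", delimiter=",", skiprows=1, ndmin=2)
        with open(path / "X.csv") as fh:
            var_names = fh.readline().strip().split(",")
        layers = {}
        for f in sorted(path.glob("layer_*.csv")):
            layers[f.stem[len("layer_"):]] = np.loadtxt(f, delimiter=",", skiprows=1, ndmin=2)
        obs = pd.read_csv(path / "obs.csv", index_col=0) if (path / "obs.csv").exists() else None
        var = pd.read_csv(path / "var.csv", index_col=0) if (path / "var.csv").exists() else None
        if obs is not None:
            obs.index = obs.index.astype(str)
        if var is not None:
            var.index = var.index.astype(str)
        obsm = {}
        for f in sorted(path.glob("obsm_*.csv")):
            obsm[f.stem[len("obsm_"):]] = np.loadtxt(f, delimiter=",", ndmin=2)
        graph = None
        if (path / "neighbor_indices.csv").exists():
            graph = NeighborGraph.from_arrays(
                np.loadtxt(path / "neighbor_indices.csv", delimiter=",", dtype=np.int64, ndmin=2),
                np.loadtxt(path / "neighbor_distances.csv", delimiter=",", ndmin=2),
            )
        if var is None:
            var = pd.DataFrame(index=pd.Index(var_names, dtype=str))
        return CellPopulation(X=X, layers=layers, obs=obs, var=var, obsm=obsm, graph=graph)
    raise ValueError(f"unknown format {format!r}")
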