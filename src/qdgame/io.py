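"""Readers and writers binding the analysis modules into reproducible runs.

Dense CSV/TSV (rows = genes, header = sample ids), MTX triplet + row/column
id sidecars, and a sample-metadata CSV (columns ``sample_id``, ``unit_id``,
``group_label`` and optionally ``stage``) on the input side; CSV reports,
GraphML and JSON bundles plus a run manifest on the output side.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionTable
from .network import SparseNetwork

logger = logging.getLogger(__name__)

REQUIRED_META_COLUMNS = ("sample_id", "unit_id", "group_label")


def read_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Dense expression matrix: rows = genes, header = sample ids."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df


def read_mtx(mtx_path: str | Path, row_ids_path: str | Path,
             col_ids_path: str | Path) -> pd.DataFrame:
    """MTX triplet file with row/column id sidecars (one id per line)."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    rows = Path(row_ids_path).read_text().split()
    cols = Path(col_ids_path).read_text().split()
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(f"MTX shape {mat.shape} does not match sidecar ids "
                         f"({len(rows)} rows, {len(cols)} cols)")
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV; indexed by sample_id."""
    meta = pd.read_csv(path)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    if "stage" not in meta.columns:
        meta["stage"] = "all"
    return meta.set_index("sample_id")


def load_table(expr_path: str | Path, meta_path: str | Path | None = None,
               mtx_sidecars: tuple | None = None) -> ExpressionTable:
    if mtx_sidecars is not None:
        values = read_mtx(expr_path, *mtx_sidecars)
    else:
        values = read_expression(expr_path)
    meta = read_metadata(meta_path) if meta_path else None
    return ExpressionTable(values, meta)


def write_table(table: ExpressionTable, expr_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    table.values.to_csv(expr_path)
    if meta_path and table.col_meta is not None:
        table.col_meta.rename_axis("sample_id").to_csv(meta_path)


def write_network(net: SparseNetwork, prefix: str | Path) -> dict:
    """Edge-list CSV, GraphML and a JSON curves bundle; returns the paths."""
    import networkx as nx

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame([{
        "source": s, "target": t, "sign": e["sign"], "weight": e["weight"],
        "net_dep": e["net_dep"], "sign_change": e["sign_change"],
    } for (t, s), e in net.edges.items()])
    edge_path = prefix.with_suffix(".edges.csv")
    edges.to_csv(edge_path, index=False)

    gml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(net.to_networkx(), gml_path)

    bundle = {
        "grid": net.grid.tolist(),
        "nodes": {str(v): {"alpha": net.node_indep[v]["alpha"],
                           "beta": net.node_indep[v]["beta"],
                           "indep_curve": np.asarray(net.node_indep[v]["curve"]).tolist(),
                           "hubness": net.hubness.get(v, 0.0)}
                  for v in net.node_ids},
        "edges": {f"{t}<-{s}": {"sign": e["sign"], "weight": e["weight"],
                                "curve": np.asarray(e["curve"]).tolist()}
                  for (t, s), e in net.edges.items()},
    }
    json_path = prefix.with_suffix(".curves.json")
    json_path.write_text(json.dumps(bundle))
    return {"edges": str(edge_path), "graphml": str(gml_path), "curves": str(json_path)}


def write_manifest(path: str | Path, *, command: str, seed: int | None,
                   parameters: dict, inputs: list | None = None) -> None:
    """Record what produced a run's outputs (inputs, seed, parameters, version)."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "inputs": [str(p) for p in (inputs or [])],
        "package_version": __version__,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
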