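"""Cell-cell interaction networks within one embryo.

Cells become network nodes and genes become the observations: each gene's
total expression over all cells (its per-gene expression index E_j) orders
the genes into a quasi-time axis, and every cell's expression across that
ordering is decomposed with exactly the same sparse qdODE machinery used for
gene networks.  Phase labels (mitotic / RA-responsive / meiotic / oogenesis)
are carried as metadata only; they never influence fitting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ExpressionTable
from .network import (SparseNetwork, classify_network_roles, fit_network)

logger = logging.getLogger(__name__)


def cell_view(table: ExpressionTable) -> tuple[ExpressionTable, np.ndarray]:
    """Transpose a genes x cells table into a cells x genes observation view.

    Rows of the result are cells (the network nodes); the observation axis
    is the genes serialized by ascending per-gene expression index
    E_j = sum over cells.  Genes with zero total expression are dropped
    (they carry no index information).  Returns (view, E_j ascending).
    """
    vals = table.values
    ej = vals.sum(axis=1)
    keep = ej > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-total gene(s) from the cell view", dropped)
    vals = vals.loc[keep]
    ej = ej.loc[keep]
    if vals.shape[0] < 5:
        raise ValueError("cell view needs at least 5 genes with nonzero totals")
    order = np.argsort(ej.to_numpy(), kind="stable")
    genes_sorted = vals.index.to_numpy()[order]
    view = ExpressionTable(vals.T[genes_sorted])  # cells x genes, sorted cols
    return view, ej.to_numpy(dtype=float)[order]


def fit_cell_network(table: ExpressionTable, phase_labels: dict | None = None,
                     max_predictors: int = 3, lop_order: int = 3,
                     seed: int = 0) -> tuple[SparseNetwork, dict, pd.DataFrame]:
    """Infer the cell-cell network of one embryo.

    ``table`` is genes x cells; ``phase_labels`` maps cell id -> phase
    annotation.  Returns (network, roles, per-phase summary) where the
    summary tallies, per phase, node counts, outgoing directional synergism
    (positive out-edges), outgoing directional antagonism (negative
    out-edges) and total outgoing hubness.
    """
    view, ej = cell_view(table)
    net = fit_network(view, ej, max_predictors=max_predictors,
                      lop_order=lop_order, seed=seed)
    roles = classify_network_roles(net)
    phases = phase_labels or {}
    net.meta["phase"] = {v: phases.get(v, "unknown") for v in net.node_ids}

    rows = []
    for phase in sorted({net.meta["phase"][v] for v in net.node_ids}):
        members = [v for v in net.node_ids if net.meta["phase"][v] == phase]
        out_pos = sum(1 for v in members for e in net.out_edges(v)
                      if net.edges[e]["sign"] > 0)
        out_neg = sum(1 for v in members for e in net.out_edges(v)
                      if net.edges[e]["sign"] < 0)
        rows.append({
            "phase": phase,
            "n_cells": len(members),
            "out_synergism": out_pos,
            "out_antagonism": out_neg,
            "total_out_hubness": float(sum(net.hubness[v] for v in members)),
            "primary_hubs": sum(1 for v in members if roles[v] == "primary_hub"),
            "secondary_hubs": sum(1 for v in members if roles[v] == "secondary_hub"),
        })
    return net, roles, pd.DataFrame(rows)
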