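"""Core containers and quasi-time index construction.

The model replaces clock time with an expression-derived index: for a gene
observed in two interacting cell types of the same unit (embryo), the *niche
index* (NI) is the per-unit sum of the gene's expression over the two types;
for network analyses the *expression index* (EI) is the total expression of a
sample over all genes (gene networks) or of a gene over all cells (cell
networks).  Units serialized in ascending index order provide the grid on
which the quasi-dynamic ODEs are integrated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative jitter applied to tied index values so the ODE grid is strictly
#: increasing (Runge-Kutta needs distinct abscissae)
TIE_JITTER = 1e-9


@dataclass
class ExpressionTable:
    """A nonnegative variables x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame, rows = variables (genes or cells), columns = samples.
    col_meta
        Optional DataFrame indexed by sample id with columns such as
        ``unit_id``, ``group_label`` (e.g. cell type) and ``stage``.
    """

    values: pd.DataFrame
    col_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values.to_numpy(), dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("expression values must be finite and nonnegative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate column ids")
        if self.col_meta is not None:
            missing = self.values.columns.difference(self.col_meta.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    @property
    def col_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def group_columns(self, group_label: str) -> list:
        """Sample ids carrying the given ``group_label`` in the metadata."""
        if self.col_meta is None:
            raise ValueError("table has no column metadata")
        mask = self.col_meta["group_label"] == group_label
        return [c for c in self.values.columns if mask.get(c, False)]


@dataclass
class IndexedSeries:
    """One variable's expression serialized along an ascending index (NI/EI)."""

    index: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.index.shape != self.values.shape:
            raise ValueError("index and values must have equal length")
        if np.any(np.diff(self.index) <= 0):
            raise ValueError("index must be strictly increasing")

    def __len__(self) -> int:
        return self.index.size


@dataclass
class PairedGeneProfile:
    """One gene's expression in two cell types across n units, with its NI.

    ``g1``/``g2`` hold the two cell-type series in original unit order, ``N``
    the per-unit niche index (always the element-wise sum ``g1 + g2``), and
    ``order`` the permutation that sorts ``N`` ascending.
    """

    gene_id: str
    g1: np.ndarray
    g2: np.ndarray
    N: np.ndarray = field(default=None)  # type: ignore[assignment]
    order: np.ndarray = field(default=None)  # type: ignore[assignment]
    unit_ids: list | None = None
    #: False when the index was supplied externally (e.g. a simulator's
    #: latent grid) rather than derived as the pair sum
    n_is_sum: bool = True

    def __post_init__(self) -> None:
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.g1.shape != self.g2.shape:
            raise ValueError("g1 and g2 must have equal length")
        if self.N is None:
            self.N = compute_niche_index(self.g1, self.g2)
        else:
            self.N = np.asarray(self.N, dtype=float)
            if self.n_is_sum and not np.allclose(self.N, self.g1 + self.g2):
                raise ValueError("N must equal g1 + g2 element-wise")
        if self.order is None:
            self.order = np.argsort(self.N, kind="stable")
        if np.any(np.diff(self.N[self.order]) < 0):
            raise ValueError("order must sort N ascending")

    @property
    def n(self) -> int:
        return self.g1.size

    def sorted_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(N, g1, g2) in ascending-NI order with tie jitter on the grid."""
        o = self.order
        grid = _break_ties(self.N[o])
        return grid, self.g1[o], self.g2[o]

    def drop_zero_units(self) -> "PairedGeneProfile":
        """Remove units where both cell types are zero (NI = 0).

        A power law with negative exponent is undefined at zero, so such
        units carry no usable index information.
        """
        keep = self.N > 0
        if not keep.all():
            logger.warning(
                "gene %s: dropping %d unit(s) with zero total expression",
                self.gene_id, int((~keep).sum()),
            )
        ids = [u for u, k in zip(self.unit_ids, keep) if k] if self.unit_ids else None
        return PairedGeneProfile(self.gene_id, self.g1[keep], self.g2[keep],
                                 N=self.N[keep], unit_ids=ids,
                                 n_is_sum=self.n_is_sum)


def compute_niche_index(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Per-unit niche index: element-wise sum of the two cell-type profiles."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("g1 and g2 must have equal length")
    if (g1 < 0).any() or (g2 < 0).any():
        raise ValueError("expression values must be nonnegative")
    return g1 + g2


def compute_expression_index(table: ExpressionTable, axis: str = "per_sample") -> np.ndarray:
    """Expression index: total expression per sample (columns) or per row.

    ``per_sample`` gives the EI of each sample (sum over genes); ``per_row``
    gives each variable's total over all samples (the per-gene EI used for
    cell-cell networks).
    """
    if table.values.size == 0:
        raise ValueError("empty expression table")
    if axis == "per_sample":
        ei = table.values.sum(axis=0).to_numpy(dtype=float)
    elif axis == "per_row":
        ei = table.values.sum(axis=1).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if (ei == 0).any():
        warnings.warn("expression index contains zeros (all-zero slices retained)")
    return ei


def _break_ties(sorted_index: np.ndarray) -> np.ndarray:
    """Make a non-decreasing index strictly increasing.

    Later duplicates get a minimal cumulative jitter proportional to the
    index range, preserving order.
    """
    out = np.array(sorted_index, dtype=float)
    span = out[-1] - out[0] if out.size > 1 else 1.0
    eps = TIE_JITTER * (span if span > 0 else max(abs(out[0]), 1.0))
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def serialize_by_index(values: np.ndarray, index: np.ndarray) -> IndexedSeries:
    """Co-sort values by ascending index; ties broken by original position."""
    values = np.asarray(values, dtype=float)
    index = np.asarray(index, dtype=float)
    if values.shape != index.shape:
        raise ValueError("values and index must have equal length")
    order = np.argsort(index, kind="stable")
    return IndexedSeries(_break_ties(index[order]), values[order])


def paired_profiles(table: ExpressionTable, group1: str, group2: str) -> list[PairedGeneProfile]:
    """Build one :class:`PairedGeneProfile` per gene from a two-group table.

    Columns are matched across the two groups by ``unit_id``; units present
    in only one group are ignored.  Units with zero total expression for a
    gene are dropped from that gene's profile.
    """
    if table.col_meta is None:
        raise ValueError("paired profiles require column metadata")
    cols1 = table.group_columns(group1)
    cols2 = table.group_columns(group2)
    units1 = {table.col_meta.loc[c, "unit_id"]: c for c in cols1}
    units2 = {table.col_meta.loc[c, "unit_id"]: c for c in cols2}
    shared = [u for u in units1 if u in units2]
    if not shared:
        raise ValueError(f"no units shared between groups {group1!r} and {group2!r}")
    m1 = table.values[[units1[u] for u in shared]].to_numpy(dtype=float)
    m2 = table.values[[units2[u] for u in shared]].to_numpy(dtype=float)
    out = []
    for r, gene in enumerate(table.values.index):
        prof = PairedGeneProfile(str(gene), m1[r], m2[r], unit_ids=list(shared))
        out.append(prof.drop_zero_units())
    return out
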