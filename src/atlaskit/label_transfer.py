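"""Reference-to-query label transfer by a transitive-connectivity majority vote.

Given a symmetric weighted kNN connectivity matrix C over reference + query
cells, the transitive connectivity C' = C @ C (neighbors of neighbors) is
used to vote: query cell q receives

    argmax_t  sum over reference cells r with label t of C'[q, r].

C' rather than C makes the vote robust (more neighbors) and connects query
cells whose direct neighbors are all queries.  Ties break lexicographically
by label; queries with zero transitive connectivity to every reference are
reported as "unassigned", never silently guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

UNASSIGNED = "unassigned"


@dataclass
class NeighborGraph:
    """Symmetric nonnegative connectivity over reference and query cells.

    ``connectivities`` is n x n CSR; ``is_query`` flags query cells;
    ``ref_labels`` holds a cell type for every reference cell (query
    entries may be anything and are ignored).
    """

    connectivities: sp.csr_matrix
    is_query: np.ndarray
    ref_labels: pd.Series
    cells: pd.Index

    def __post_init__(self) -> None:
        C = sp.csr_matrix(self.connectivities)
        self.connectivities = C
        self.is_query = np.asarray(self.is_query, dtype=bool)
        self.cells = pd.Index(self.cells)
        n = C.shape[0]
        if C.shape != (n, n) or len(self.is_query) != n or len(self.cells) != n:
            raise ValidationError("graph dimensions are inconsistent")
        if C.nnz and C.data.min() < 0:
            raise ValidationError("connectivities must be nonnegative")
        if (abs(C - C.T)).max() > 1e-12 * max(1.0, abs(C).max()):
            raise ValidationError("connectivity matrix must be symmetric")
        self.ref_labels = self.ref_labels.reindex(self.cells)
        ref_missing = self.ref_labels[~self.is_query].isna()
        if ref_missing.any():
            raise ValidationError(
                f"{int(ref_missing.sum())} reference cells lack a label"
            )
        if (~self.is_query).sum() == 0:
            raise ValidationError("graph has no reference cells")

    @property
    def n_cells(self) -> int:
        return self.connectivities.shape[0]


def build_knn_graph(embedding: pd.DataFrame, n_neighbors: int,
                    is_query=None, ref_labels: pd.Series | None = None
                    ) -> NeighborGraph:
    """Symmetric kNN graph on Euclidean distances in a latent embedding.

    Each cell connects to its ``n_neighbors`` nearest neighbors with weight
    1 / (1 + distance) (any positive, decreasing kernel works; this one is
    the package default), symmetrized by the elementwise maximum of the
    directed weights.
    """
    cells = pd.Index(embedding.index)
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValidationError(f"n_neighbors={n_neighbors} needs more than {n} cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), n_neighbors)
    W = sp.csr_matrix((1.0 / (1.0 + dist.ravel()), (rows, idx.ravel())), shape=(n, n))
    C = W.maximum(W.T)
    if is_query is None:
        is_query = np.zeros(n, dtype=bool)
    if ref_labels is None:
        ref_labels = pd.Series(pd.NA, index=cells)
    return NeighborGraph(connectivities=C, is_query=np.asarray(is_query, dtype=bool),
                         ref_labels=ref_labels, cells=cells)


def transitive_connectivity(g: NeighborGraph) -> sp.csr_matrix:
    """C' = C @ C (matrix product); symmetric and nonnegative."""
    C = g.connectivities
    if not np.all(np.isfinite(C.data)):
        raise ValidationError("connectivities must be finite")
    return (C @ C).tocsr()


def transfer_labels(g: NeighborGraph) -> pd.DataFrame:
    """Vote cell types onto query cells via C' = C @ C.

    Returns one row per query cell with columns ``label`` (winning type or
    ``"unassigned"``), ``margin`` (winning minus runner-up vote mass) and
    ``tie`` (True when the top vote was shared and broken lexicographically).
    """
    Cp = transitive_connectivity(g)
    q_idx = np.flatnonzero(g.is_query)
    r_idx = np.flatnonzero(~g.is_query)
    if len(q_idx) == 0:
        return pd.DataFrame(columns=["label", "margin", "tie"])
    labels = np.asarray(g.ref_labels.iloc[r_idx])
    label_set = sorted(set(labels))
    onehot = sp.csr_matrix(
        (np.ones(len(r_idx)),
         (np.arange(len(r_idx)), [label_set.index(l) for l in labels])),
        shape=(len(r_idx), len(label_set)),
    )
    votes = np.asarray((Cp[q_idx][:, r_idx] @ onehot).todense())  # q x labels
    out = []
    for row in votes:
        total = row.sum()
        if total == 0:
            out.append((UNASSIGNED, 0.0, False))
            continue
        best = int(np.argmax(row))  # first max = lexicographically smallest label
        top = row[best]
        tie = bool(np.sum(row == top) > 1)
        runner_up = np.max(np.delete(row, best)) if len(row) > 1 else 0.0
        out.append((label_set[best], float(top - runner_up), tie))
    return pd.DataFrame(out, columns=["label", "margin", "tie"],
                        index=g.cells[q_idx])
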