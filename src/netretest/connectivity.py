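"""Network functional connectivity matrices and magnitude thresholding.

Each scan's node time series give a symmetric node-by-node association
matrix (Pearson correlation by default; sample covariance available).  The
matrix is then thresholded at a fixed value (default 0.1): an edge is kept,
with its signed value, iff its magnitude strictly exceeds the threshold —
the rule applies identically to positive and negative connections — and the
diagonal is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScanTimeSeries, ValidationError


@dataclass
class ConnectivityMatrix:
    """Symmetric signed association matrix for one scan."""

    values: np.ndarray
    kind: str  # "correlation" or "covariance"
    subject: str = ""
    session: str = ""
    condition: str = ""
    network: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("correlation", "covariance"):
            raise ValidationError(f"unknown connectivity kind: {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("connectivity values must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("connectivity matrix is not symmetric")
        if self.kind == "correlation":
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
                raise ValidationError("correlation matrix must have unit diagonal")
            if np.any(np.abs(self.values) > 1.0 + 1e-8):
                raise ValidationError("correlation entries must lie in [-1, 1]")
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(self.values.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with node labels as header row and index column."""
        pd.DataFrame(self.values, index=self.node_labels,
                     columns=self.node_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "correlation",
                 **meta: str) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), kind=kind,
                   node_labels=list(df.columns), **meta)


@dataclass
class ThresholdedGraph:
    """Signed weighted adjacency after magnitude thresholding, with binary support."""

    weights: np.ndarray
    support: np.ndarray
    threshold: float
    subject: str = ""
    session: str = ""
    condition: str = ""
    network: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.weights.shape != self.support.shape:
            raise ValidationError("weights and support must have the same shape")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("thresholded graph diagonal must be zero")
        if not np.array_equal(self.support, self.weights != 0):
            raise ValidationError("support must mark exactly the nonzero weights")
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(self.weights.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.support.sum() // 2)


def compute_nfc(scan: ScanTimeSeries, kind: str = "correlation") -> ConnectivityMatrix:
    """Node-by-node association matrix of one scan.

    ``correlation`` gives Pearson correlations; ``covariance`` the sample
    covariance with denominator n-1.  Constant node series make the
    correlation undefined and raise an error naming the node.
    """
    if kind not in ("correlation", "covariance"):
        raise ValidationError(f"unknown connectivity kind: {kind!r}")
    if scan.n_timepoints < 3:
        raise ValidationError("need at least 3 timepoints to estimate connectivity")
    data = scan.data
    if kind == "correlation":
        sd = data.std(axis=1)
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            bad = ", ".join(scan.node_labels[i] for i in constant)
            raise ValidationError(
                f"constant node series (correlation undefined): {bad}"
            )
        values = np.corrcoef(data)
        values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
    else:
        values = np.cov(data, ddof=1)
        values = (values + values.T) / 2.0
    return ConnectivityMatrix(
        values=values, kind=kind, subject=scan.subject, session=scan.session,
        condition=scan.condition, network=scan.network,
        node_labels=list(scan.node_labels),
    )


def threshold_matrix(C: ConnectivityMatrix, tau: float = 0.1) -> ThresholdedGraph:
    """Keep edge (i, j), i != j, with its signed value iff |C[i, j]| > tau.

    The inequality is strict; the diagonal is always removed.  ``tau = 0``
    therefore retains every nonzero off-diagonal entry.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    W = C.values.copy()
    np.fill_diagonal(W, 0.0)
    support = np.abs(W) > tau
    W[~support] = 0.0
    return ThresholdedGraph(
        weights=W, support=support, threshold=float(tau),
        subject=C.subject, session=C.session, condition=C.condition,
        network=C.network, node_labels=list(C.node_labels),
    )
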