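"""Shared containers, exceptions and seeding helpers.

The atomic unit of the pipeline is a :class:`ScanTimeSeries`: the node-by-time
matrix of one functional scan, tagged with (subject, session, condition,
network) labels and the repetition time of the acquisition.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("netretest")


def get_logger(name: str = "netretest") -> logging.Logger:
    return logging.getLogger(name)


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class NetretestError(Exception):
    """Base class for all package errors."""


class ValidationError(NetretestError, ValueError):
    """Invalid input data or configuration."""


class UndefinedRatioError(NetretestError, ZeroDivisionError):
    """A variance ratio with zero numerator and denominator."""


class PositiveDefiniteProjectionError(NetretestError):
    """Projection to a positive-definite matrix failed to converge."""


class RankDeficientDesignError(ValidationError):
    """Confound design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "confound design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def substream_rng(seed: int, *labels: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by a label tuple.

    The labels are hashed with SHA-256 so the stream depends only on the
    (seed, labels) pair, never on the order in which scans are generated.
    """
    key = "\x1f".join(str(x) for x in labels).encode()
    digest = hashlib.sha256(key).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


# ---------------------------------------------------------------------------
# ScanTimeSeries
# ---------------------------------------------------------------------------

@dataclass
class ScanTimeSeries:
    """One scan's node-by-timepoint matrix with acquisition metadata.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_nodes, n_timepoints)``; no missing values.
    tr_seconds
        Repetition time of the acquisition, in seconds.
    subject, session, condition, network
        Labels identifying the scan within the cohort design.
    node_labels
        Optional node names; defaults to ``n0 .. n{k-1}``.
    """

    data: np.ndarray
    tr_seconds: float
    subject: str
    session: str
    condition: str
    network: str
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("scan data must be a 2-D (nodes x timepoints) matrix")
        n_nodes, n_t = self.data.shape
        if n_nodes < 2:
            raise ValidationError("a scan needs at least 2 nodes")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(
                f"scan {self.key()} contains non-finite values"
            )
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(n_nodes)]
        if len(self.node_labels) != n_nodes:
            raise ValidationError("node_labels length must match node count")
        if n_t <= 10 * n_nodes:
            logger.warning(
                "scan %s has only %d timepoints for %d nodes "
                "(>10x nodes recommended)", self.key(), n_t, n_nodes
            )

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def key(self) -> tuple[str, str, str, str]:
        return (self.subject, self.session, self.condition, self.network)

    def with_data(self, data: np.ndarray) -> "ScanTimeSeries":
        """Copy of this scan with the data matrix replaced, metadata kept."""
        return replace(self, data=np.asarray(data, dtype=float))
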