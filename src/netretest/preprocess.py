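"""Node-level confound regression and temporal band-pass filtering.

The preprocessing applied to each scan's node time series mirrors the
node-relevant tail of a standard resting-state pipeline: nuisance signals
(six rigid-body motion parameters and their first temporal derivatives,
plus CSF / white-matter / whole-brain global signals — 15 columns in the
standard set) are regressed out by ordinary least squares, and the
residuals are band-pass filtered to 0.01-0.1 Hz with a zero-phase
Butterworth filter.

Regression runs before filtering; the order is fixed and documented rather
than configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .core import RankDeficientDesignError, ScanTimeSeries, ValidationError


@dataclass
class ConfoundSet:
    """Nuisance regressors for one scan: a (timepoints x k) matrix with names."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.size == 0:
            self.regressors = self.regressors.reshape(0, 0)
        if self.regressors.ndim != 2:
            raise ValidationError("confound regressors must be 2-D (timepoints x k)")
        k = self.regressors.shape[1]
        if len(self.names) != k:
            raise ValidationError(f"got {len(self.names)} names for {k} regressors")
        if not np.all(np.isfinite(self.regressors)):
            raise ValidationError("confound regressors contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]

    def with_derivatives(self) -> "ConfoundSet":
        """Append first temporal derivatives (backward differences, first
        sample zero-padded) of every column."""
        deriv = np.diff(self.regressors, axis=0, prepend=self.regressors[:1])
        deriv[0, :] = 0.0
        return ConfoundSet(
            regressors=np.hstack([self.regressors, deriv]),
            names=self.names + [f"{n}_derivative" for n in self.names],
        )

    @classmethod
    def empty(cls, n_timepoints: int) -> "ConfoundSet":
        return cls(regressors=np.empty((n_timepoints, 0)), names=[])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfoundSet":
        """Read a confound TSV: header row of column names, one row per timepoint."""
        df = pd.read_csv(path, sep="\t")
        return cls(regressors=df.to_numpy(dtype=float), names=list(df.columns))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.regressors, columns=self.names).to_csv(
            path, sep="\t", index=False
        )


def standard_confound_set(
    motion: np.ndarray,
    csf: np.ndarray | None = None,
    white_matter: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    motion_names: list[str] | None = None,
) -> ConfoundSet:
    """Assemble the standard 15-column nuisance set: six motion parameters,
    their first temporal derivatives, and the three global signals (CSF,
    white matter, whole brain).  Any global column may be omitted."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValidationError("motion must be a (timepoints x 6) matrix")
    names = motion_names or ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    base = ConfoundSet(motion, list(names)).with_derivatives()
    cols, extra_names = [base.regressors], list(base.names)
    for sig, name in ((csf, "csf"), (white_matter, "white_matter"),
                      (global_signal, "global_signal")):
        if sig is not None:
            cols.append(np.asarray(sig, dtype=float).reshape(-1, 1))
            extra_names.append(name)
    return ConfoundSet(np.hstack(cols), extra_names)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # QR with column pivoting: columns whose R diagonal collapses are the
    # ones that add no rank.
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return bad or list(names)


def regress_confounds(
    scan: ScanTimeSeries, confounds: ConfoundSet | None = None
) -> ScanTimeSeries:
    """Replace each node's series by its OLS residual against
    [intercept | confounds].

    With an empty confound set this is plain demeaning.  Residuals are
    orthogonal to every design column.  A rank-deficient design raises
    :class:`RankDeficientDesignError` naming the collinear columns.
    """
    T = scan.n_timepoints
    if confounds is None:
        confounds = ConfoundSet.empty(T)
    if confounds.n_timepoints != T and confounds.n_regressors > 0:
        raise ValidationError(
            f"confounds have {confounds.n_timepoints} timepoints, scan has {T}"
        )
    names = ["intercept"] + list(confounds.names)
    X = np.column_stack([np.ones(T), confounds.regressors.reshape(T, -1)]) \
        if confounds.n_regressors else np.ones((T, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError(_collinear_columns(X, names))
    beta, *_ = np.linalg.lstsq(X, scan.data.T, rcond=None)
    resid = scan.data.T - X @ beta
    return scan.with_data(resid.T)


def bandpass(
    scan: ScanTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> ScanTimeSeries:
    """Zero-phase Butterworth band-pass of every node series.

    A Butterworth of the given order is applied forward and backward
    (``sosfiltfilt``), doubling the effective attenuation and cancelling
    phase distortion.  The DC component is removed, so output node means
    are ~0.
    """
    fs = 1.0 / scan.tr_seconds
    nyquist = fs / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValidationError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValidationError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR={scan.tr_seconds} s"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, scan.data, axis=1)
    return scan.with_data(filtered)


def preprocess_scan(
    scan: ScanTimeSeries,
    confounds: ConfoundSet | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ScanTimeSeries:
    """Confound regression followed by band-pass filtering (fixed order)."""
    return bandpass(regress_confounds(scan, confounds), low_hz=low_hz, high_hz=high_hz)
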