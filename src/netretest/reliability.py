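"""ICC(3,1) test-retest reliability of scan-wise graph metrics.

For each (network, condition, metric) cell the subjects-by-sessions matrix of
scan-wise values enters a two-way mixed-effects ANOVA (subjects random,
sessions fixed), and the consistency intraclass correlation is

    ICC(3,1) = (MSp - MSe) / (MSp + (d - 1) * MSe)

with MSp the between-subject mean square, MSe the residual mean square and
d the number of observations (sessions) per subject.  Because the session
main effect is removed by the two-way decomposition, a constant session
offset does not lower the ICC (consistency, not absolute agreement).

Negative raw ICCs are hard to interpret and are clamped to 0 — both the raw
and the clamped value are always reported.  ICCs are categorised into the
conventional bands: poor [0, 0.2), fair [0.2, 0.4), moderate [0.4, 0.6),
good [0.6, 0.8), excellent [0.8, 1].  The bands are half-open so the printed
gaps (0.79 vs 0.8 and so on) are closed without ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError, get_logger
from .metrics import ScanMetricRecord

logger = get_logger(__name__)

CATEGORY_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "excellent"),
)


@dataclass
class IccDecomposition:
    """Mean squares and degrees of freedom of the two-way ANOVA."""

    ms_subjects: float
    ms_sessions: float
    ms_error: float
    df_subjects: int
    df_sessions: int
    df_error: int


@dataclass
class ReliabilityRecord:
    """ICC(3,1) for one (network, condition, metric) cell."""

    network: str
    condition: str
    metric: str
    icc_raw: float
    icc: float
    category: str
    n_subjects: int
    d: int
    decomposition: IccDecomposition | None = None


def _icc31_stack(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ICC(3,1) over a stack of subjects-by-sessions matrices.

    ``X`` has shape (..., n, d).  Returns (icc_raw, ms_subjects,
    ms_sessions, ms_error) broadcast over the leading axes.  Cells with zero
    denominator (no variance at all) get icc_raw = 0.
    """
    n, d = X.shape[-2], X.shape[-1]
    grand = X.mean(axis=(-2, -1), keepdims=True)
    subj_mean = X.mean(axis=-1, keepdims=True)
    sess_mean = X.mean(axis=-2, keepdims=True)
    ss_subj = d * ((subj_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_sess = n * ((sess_mean - grand) ** 2).sum(axis=(-2, -1))
    ss_total = ((X - grand) ** 2).sum(axis=(-2, -1))
    ss_err = np.maximum(ss_total - ss_subj - ss_sess, 0.0)
    msp = ss_subj / (n - 1)
    mss = ss_sess / (d - 1)
    mse = ss_err / ((n - 1) * (d - 1))
    denom = msp + (d - 1) * mse
    with np.errstate(divide="ignore", invalid="ignore"):
        icc_raw = np.where(denom > 0, (msp - mse) / np.where(denom > 0, denom, 1.0), 0.0)
    return icc_raw, msp, mss, mse


def icc_3_1(
    values: np.ndarray,
    network: str = "",
    condition: str = "",
    metric: str = "",
) -> tuple[ReliabilityRecord, IccDecomposition]:
    """ICC(3,1) of a subjects-by-sessions value matrix.

    Rows with any missing value are dropped (listwise deletion, logged);
    at least 3 complete subjects and 2 sessions are required.  A matrix with
    zero total variance yields ``icc_raw = 0`` with a warning.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValidationError("values must be a 2-D subjects x sessions matrix")
    complete = np.all(np.isfinite(X), axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "icc_3_1(%s, %s, %s): dropped %d subjects with missing values",
            network, condition, metric, n_dropped,
        )
        X = X[complete]
    n, d = X.shape
    if n < 3:
        raise ValidationError(f"need >= 3 complete subjects, got {n}")
    if d < 2:
        raise ValidationError(f"need >= 2 sessions, got {d}")
    if np.ptp(X) == 0:
        warnings.warn("zero total variance; ICC set to 0", stacklevel=2)
    icc_raw, msp, mss, mse = _icc31_stack(X)
    icc_raw = float(icc_raw)
    icc = max(icc_raw, 0.0)
    decomp = IccDecomposition(
        ms_subjects=float(msp),
        ms_sessions=float(mss),
        ms_error=float(mse),
        df_subjects=n - 1,
        df_sessions=d - 1,
        df_error=(n - 1) * (d - 1),
    )
    record = ReliabilityRecord(
        network=network, condition=condition, metric=metric,
        icc_raw=icc_raw, icc=icc, category=categorize_icc(icc),
        n_subjects=n, d=d, decomposition=decomp,
    )
    return record, decomp


def categorize_icc(icc: float) -> str:
    """Reliability band of a clamped ICC: poor/fair/moderate/good/excellent."""
    if not (0.0 <= icc <= 1.0 + 1e-12):
        raise ValidationError(f"icc must lie in [0, 1], got {icc}")
    for upper, label in CATEGORY_BANDS:
        if icc < upper:
            return label
    return "excellent"  # pragma: no cover


def records_to_frame(records: list[ScanMetricRecord]) -> pd.DataFrame:
    """Long-format metrics table: one row per (scan, metric)."""
    rows = []
    for r in records:
        for metric, value in r.metric_values().items():
            rows.append((r.subject, r.session, r.condition, r.network, metric,
                         value, r.n_nodes, r.n_edges, r.n_disconnected_pairs))
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "condition", "network", "metric", "value",
                 "n_nodes", "n_edges", "n_disconnected_pairs"],
    )


def _check_balanced(df: pd.DataFrame) -> None:
    sess_sets = df.groupby(["subject", "condition", "network"])["session"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    unique_sets = sess_sets.unique()
    if len(unique_sets) > 1:
        ref = max(unique_sets, key=len)
        offenders = sess_sets[sess_sets != ref]
        raise ValidationError(
            "unbalanced sessions across (subject, condition, network): "
            + "; ".join(f"{idx} -> {val}" for idx, val in offenders.items())
        )


def reliability_table(
    records: list[ScanMetricRecord] | pd.DataFrame,
) -> list[ReliabilityRecord]:
    """One ICC(3,1) record per (network x condition x metric) cell.

    Accepts either ScanMetricRecord objects or an equivalent long-format
    DataFrame.  Every (subject, condition, network) must carry the same
    session set; violations raise an error listing the offenders.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValidationError("no scan metric records provided")
    _check_balanced(df)
    out: list[ReliabilityRecord] = []
    sessions = sorted(df["session"].unique())
    for (network, condition, metric), cell in df.groupby(
        ["network", "condition", "metric"], sort=True
    ):
        wide = cell.pivot_table(
            index="subject", columns="session", values="value", aggfunc="first"
        ).reindex(columns=sessions)
        record, _ = icc_3_1(
            wide.to_numpy(), network=network, condition=condition, metric=metric
        )
        out.append(record)
    return out


def reliability_to_frame(records: list[ReliabilityRecord]) -> pd.DataFrame:
    """CSV-ready table of reliability records, one row per cell."""
    rows = []
    for r in records:
        dec = r.decomposition
        rows.append((
            r.network, r.condition, r.metric, r.n_subjects, r.d,
            dec.ms_subjects if dec else np.nan,
            dec.ms_sessions if dec else np.nan,
            dec.ms_error if dec else np.nan,
            r.icc_raw, r.icc, r.category,
        ))
    return pd.DataFrame(
        rows,
        columns=["network", "condition", "metric", "n_subjects", "d",
                 "ms_subjects", "ms_sessions", "ms_error",
                 "icc_raw", "icc", "category"],
    )
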