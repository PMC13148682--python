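"""Permutation inference for ICC differences between scan conditions.

No consensus parametric test exists for comparing intraclass correlations,
so condition differences are tested by permutation: under the null that two
conditions share the same reliability, each subject's pair of session rows
is exchangeable between the two condition labels.  A null draw therefore
swaps, independently per subject with probability 1/2, the subject's full
session row between conditions — both sessions move together, preserving
the within-subject pairing the ICC depends on — and recomputes the ICC
difference on the clamped ICCs, exactly as in the observed statistic.

The two-sided p-value uses +1 smoothing, p = (1 + #{|null| >= |obs|}) /
(B + 1), so it is never exactly zero and never below 1/(B+1).  Across the
family of (network x metric x movie-vs-rest) tests, p-values are adjusted
with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, get_logger
from .metrics import METRIC_NAMES, ScanMetricRecord
from .reliability import _icc31_stack, records_to_frame

logger = get_logger(__name__)


@dataclass
class PermutationResult:
    """One two-condition ICC-difference permutation test."""

    network: str
    metric: str
    condition_a: str
    condition_b: str
    icc_a: float
    icc_b: float
    observed_diff: float
    null_q025: float
    null_q975: float
    p_value: float
    n_permutations: int
    seed: int
    q_value: float = float("nan")


def _clamped_icc(X: np.ndarray) -> np.ndarray:
    icc_raw, *_ = _icc31_stack(X)
    return np.maximum(icc_raw, 0.0)


def permute_icc_diff(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    network: str = "",
    metric: str = "",
    condition_a: str = "",
    condition_b: str = "",
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test of icc(values_a) - icc(values_b) (clamped ICCs).

    ``values_a`` and ``values_b`` are subjects-by-sessions matrices with the
    same subjects in the same row order.  The null swaps each subject's row
    between conditions with probability 1/2.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape != B.shape:
        raise ValidationError(
            f"condition matrices must share subjects and sessions; got "
            f"{A.shape} vs {B.shape}"
        )
    if A.ndim != 2 or A.shape[0] < 3 or A.shape[1] < 2:
        raise ValidationError("need >= 3 subjects and >= 2 sessions per condition")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; p-value resolution is "
            f"only {1.0 / (n_permutations + 1):.3g}", stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    icc_a = float(_clamped_icc(A))
    icc_b = float(_clamped_icc(B))
    observed = icc_a - icc_b

    swap = rng.random((n_permutations, A.shape[0])) < 0.5  # (B, n) per-subject flips
    mask = swap[:, :, None]
    perm_a = np.where(mask, B[None, :, :], A[None, :, :])
    perm_b = np.where(mask, A[None, :, :], B[None, :, :])
    null = _clamped_icc(perm_a) - _clamped_icc(perm_b)

    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_permutations + 1.0)
    q025, q975 = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        network=network, metric=metric,
        condition_a=condition_a, condition_b=condition_b,
        icc_a=icc_a, icc_b=icc_b, observed_diff=observed,
        null_q025=float(q025), null_q975=float(q975),
        p_value=float(p), n_permutations=int(n_permutations), seed=int(seed),
    )


def fdr_bh(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone, capped at 1, input order preserved.  Values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("p_values must be nonempty")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def run_family(
    records: list[ScanMetricRecord] | pd.DataFrame,
    baseline_condition: str = "RS",
    n_permutations: int = 5000,
    seed: int = 0,
) -> list[PermutationResult]:
    """All (network x metric x condition-vs-baseline) permutation tests,
    with q-values computed over the whole family.

    With 14 networks, 5 metrics and 3 non-baseline conditions this is the
    210-test family; each test gets its own deterministic RNG substream so
    family composition never changes individual tests.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    conditions = sorted(df["condition"].unique())
    if baseline_condition not in conditions:
        raise ValidationError(
            f"baseline condition {baseline_condition!r} not present in data "
            f"(have: {conditions})"
        )
    others = [c for c in conditions if c != baseline_condition]
    networks = sorted(df["network"].unique())
    metrics = [m for m in METRIC_NAMES if m in set(df["metric"])]
    sessions = sorted(df["session"].unique())

    def cell_matrix(network: str, condition: str, metric: str) -> tuple[np.ndarray, list]:
        cell = df[(df["network"] == network) & (df["condition"] == condition)
                  & (df["metric"] == metric)]
        wide = cell.pivot_table(index="subject", columns="session",
                                values="value", aggfunc="first").reindex(columns=sessions)
        return wide.to_numpy(), list(wide.index)

    results: list[PermutationResult] = []
    from .core import substream_rng
    for network in networks:
        for metric in metrics:
            base_X, base_subjects = cell_matrix(network, baseline_condition, metric)
            for condition in others:
                X, subjects = cell_matrix(network, condition, metric)
                if subjects != base_subjects:
                    raise ValidationError(
                        f"subject sets differ between {condition} and "
                        f"{baseline_condition} for ({network}, {metric})"
                    )
                rng = substream_rng(seed, "perm", network, metric, condition)
                results.append(
                    permute_icc_diff(
                        X, base_X, n_permutations=n_permutations, seed=seed,
                        network=network, metric=metric,
                        condition_a=condition, condition_b=baseline_condition,
                        rng=rng,
                    )
                )
    q = fdr_bh([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def permutation_to_frame(results: list[PermutationResult]) -> pd.DataFrame:
    """CSV-ready table mirroring PermutationResult fields."""
    return pd.DataFrame(
        [(r.network, r.metric, r.condition_a, r.condition_b, r.icc_a, r.icc_b,
          r.observed_diff, r.null_q025, r.null_q975, r.p_value, r.q_value,
          r.n_permutations, r.seed) for r in results],
        columns=["network", "metric", "condition_a", "condition_b", "icc_a",
                 "icc_b", "observed_diff", "null_q025", "null_q975",
                 "p_value", "q_value", "n_permutations", "seed"],
    )
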