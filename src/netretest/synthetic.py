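"""Synthetic multi-session cohort generator with known edge-level reliability.

The generator emulates the acquisition geometry of a two-cohort naturalistic
viewing study — 33 subjects, 2 sessions, four scan conditions (one resting
state and three movies), 14 node networks of 9-23 nodes, TR 0.719 s, 834
timepoints per 10-minute scan — under a variance-components model in which
each edge's latent connectivity is

    w[s, t] = base + b[s] + e[s, t],   b ~ N(0, sigma_between^2),
                                        e ~ N(0, sigma_within^2),

independently per upper-triangle edge and mirrored for symmetry.  The
population intraclass correlation of every edge is therefore the analytically
known ratio sigma_between^2 / (sigma_between^2 + sigma_within^2), which is
what downstream ICC(3,1) estimation should recover (attenuated only by the
finite-timepoint sampling noise of the empirical connectivity estimate).

Each scan's node time series are drawn as i.i.d. multivariate Gaussian
samples whose covariance is the session's latent matrix, projected to the
nearest positive-definite correlation matrix by eigenvalue clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    PositiveDefiniteProjectionError,
    ScanTimeSeries,
    UndefinedRatioError,
    ValidationError,
    substream_rng,
)

#: Canonical names of the 14 meta-analytic networks (eMDN is also known as
#: extDMN in parts of the literature; the two are aliases).
DEFAULT_NETWORK_NAMES: tuple[str, ...] = (
    "AM", "CogAC", "eMDN", "EmoSF", "Empathy", "ER", "eSAD",
    "MNS", "Motor", "Rew", "SM", "ToM", "VigAtt", "WM",
)

#: Network sizes spanning the 9-23 node range of the emulated atlas.
DEFAULT_NETWORK_SIZES: tuple[int, ...] = (
    9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 21, 22, 23,
)

DEFAULT_CONDITIONS: tuple[str, ...] = ("RS", "Inscapes", "Circus", "Jones")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``sigma_between`` and ``sigma_within`` are the standard deviations of the
    subject-level and session-level edge deviations; their defaults
    (0.18, 0.09) give every edge a theoretical ICC of 0.8 with a total
    edge-weight spread (sd ~0.2) small enough that latent matrices rarely
    need positive-definite repair.
    """

    n_subjects: int = 33
    n_sessions: int = 2
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    network_names: tuple[str, ...] | None = None
    n_timepoints: int = 834
    tr_seconds: float = 0.719
    sigma_between: float = 0.18
    sigma_within: float = 0.09
    base_connectivity: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0
    #: Optional per-condition multiplier on sigma_within; lets tests plant
    #: a "this condition is more reliable" effect.  Default: no effect.
    sigma_within_multipliers: dict[str, float] = field(default_factory=dict)
    pd_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.network_sizes = tuple(int(s) for s in self.network_sizes)
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.n_sessions < 2:
            raise ValidationError("n_sessions must be >= 2")
        if not self.conditions:
            raise ValidationError("at least one condition is required")
        if any(s < 2 or s > 100 for s in self.network_sizes):
            raise ValidationError("network sizes must lie in [2, 100]")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("sigma_between and sigma_within must be >= 0")
        if not (-1.0 < self.base_connectivity < 1.0):
            raise ValidationError("base_connectivity must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.network_names is None:
            self.network_names = tuple(
                DEFAULT_NETWORK_NAMES[i] if i < len(DEFAULT_NETWORK_NAMES) else f"NET{i}"
                for i in range(len(self.network_sizes))
            )
        else:
            self.network_names = tuple(self.network_names)
        if len(self.network_names) != len(self.network_sizes):
            raise ValidationError("network_names must match network_sizes in length")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"sub{i + 1:02d}" for i in range(self.n_subjects))

    @property
    def sessions(self) -> tuple[str, ...]:
        return tuple(f"ses{j + 1}" for j in range(self.n_sessions))

    def sigma_within_for(self, condition: str) -> float:
        return self.sigma_within * self.sigma_within_multipliers.get(condition, 1.0)


@dataclass
class GroundTruth:
    """Latent edge weights and their theoretical ICC for every cohort cell.

    ``latent``: (subject, condition, network) -> subject-level latent matrix
    (base + subject deviation, unit diagonal, pre-projection).
    ``session_targets``: (subject, session, condition, network) -> the
    positive-definite sampling target actually used for that scan, i.e. the
    post-projection truth for empirical covariance checks.
    ``edge_icc``: (condition, network) -> per-edge theoretical ICC matrix
    (constant off-diagonal under the i.i.d. edge model).
    """

    latent: dict[tuple[str, str, str], np.ndarray]
    session_targets: dict[tuple[str, str, str, str], np.ndarray]
    edge_icc: dict[tuple[str, str], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject, condition, network, node_i, node_j,
        latent_weight, theoretical_icc (upper triangle only)."""
        rows = []
        for (subject, condition, network), mat in self.latent.items():
            icc = self.edge_icc[(condition, network)]
            n = mat.shape[0]
            iu, ju = np.triu_indices(n, k=1)
            for i, j in zip(iu, ju):
                rows.append(
                    (subject, condition, network, int(i), int(j),
                     float(mat[i, j]), float(icc[i, j]))
                )
        return pd.DataFrame(
            rows,
            columns=["subject", "condition", "network", "node_i", "node_j",
                     "latent_weight", "theoretical_icc"],
        )


def theoretical_icc(sigma_between: float, sigma_within: float) -> float:
    """Population ICC implied by the variance components.

    Returns sigma_between^2 / (sigma_between^2 + sigma_within^2), the
    consistency intraclass correlation a two-way ANOVA targets when subject
    and session effects are additive.
    """
    if sigma_between < 0 or sigma_within < 0:
        raise ValidationError("variance components must be >= 0")
    denom = sigma_between**2 + sigma_within**2
    if denom == 0:
        raise UndefinedRatioError(
            "theoretical ICC is undefined when both variance components are zero"
        )
    return sigma_between**2 / denom


def nearest_positive_definite(
    matrix: np.ndarray, tolerance: float = 1e-8, restandardize: bool = True
) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite one.

    Uses eigenvalue clipping: eigenvalues below ``tolerance`` are raised to
    ``tolerance`` and the matrix reconstructed, which minimises Frobenius
    distance among symmetric matrices with that eigenvalue floor.  When
    ``restandardize`` is true the result is rescaled to unit diagonal
    (clip-and-rescale iterated until the floor holds), so a correlation-like
    input stays correlation-like.  An input already satisfying the bound is
    returned unchanged.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("input must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("input matrix is not symmetric")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    eff_tol = max(tolerance, 0.0)
    # clip with headroom: re-standardisation divides eigenvalues by up to
    # max(diag), so clipping exactly at the floor can oscillate just below it
    clip_floor = max(eff_tol * 10.0, 1e-15)
    for _ in range(200):
        w, V = np.linalg.eigh(A)
        if w.min() >= eff_tol:
            return A
        w = np.clip(w, clip_floor, None)
        A = (V * w) @ V.T
        A = (A + A.T) / 2.0
        if restandardize:
            d = np.sqrt(np.diag(A))
            A = A / np.outer(d, d)
            np.fill_diagonal(A, 1.0)
    raise PositiveDefiniteProjectionError(
        f"projection did not reach eigenvalue floor {eff_tol} in 200 iterations"
    )


def _symmetric_deviation(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Symmetric matrix with i.i.d. N(0, sd^2) upper-triangle entries, zero diagonal."""
    D = np.zeros((n, n))
    if sd > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        vals = rng.normal(0.0, sd, size=iu.size)
        D[iu, ju] = vals
        D[ju, iu] = vals
    return D


def generate_latent_matrices(config: SimulationConfig) -> GroundTruth:
    """Draw subject-level latent matrices and session-level sampling targets.

    For each (subject, condition, network): latent = base matrix plus a
    symmetric subject deviation (per-edge sd ``sigma_between``).  For each
    session the sampling target is the latent plus a symmetric session
    deviation (per-edge sd ``sigma_within``, optionally scaled per
    condition), diagonal pinned at 1, then projected to positive definite.
    """
    latent: dict[tuple[str, str, str], np.ndarray] = {}
    targets: dict[tuple[str, str, str, str], np.ndarray] = {}
    edge_icc: dict[tuple[str, str], np.ndarray] = {}

    for network, size in zip(config.network_names, config.network_sizes):
        base = np.full((size, size), config.base_connectivity)
        np.fill_diagonal(base, 1.0)
        for condition in config.conditions:
            sw = config.sigma_within_for(condition)
            icc_mat = np.zeros((size, size))
            if config.sigma_between > 0 or sw > 0:
                icc_val = theoretical_icc(config.sigma_between, sw)
                icc_mat[:] = icc_val
            np.fill_diagonal(icc_mat, 1.0)
            edge_icc[(condition, network)] = icc_mat
            for subject in config.subjects:
                rng_b = substream_rng(config.seed, "subject-dev", subject, condition, network)
                L = base + _symmetric_deviation(rng_b, size, config.sigma_between)
                np.fill_diagonal(L, 1.0)
                latent[(subject, condition, network)] = L
                for session in config.sessions:
                    rng_w = substream_rng(
                        config.seed, "session-dev", subject, session, condition, network
                    )
                    T = L + _symmetric_deviation(rng_w, size, sw)
                    np.fill_diagonal(T, 1.0)
                    targets[(subject, session, condition, network)] = (
                        nearest_positive_definite(T, config.pd_tolerance)
                    )
    return GroundTruth(latent=latent, session_targets=targets, edge_icc=edge_icc)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[ScanTimeSeries], GroundTruth]:
    """Generate every scan of the cohort.

    Each scan draws ``n_timepoints`` multivariate Gaussian samples with
    covariance equal to the session's positive-definite target (via Cholesky
    factorisation) and adds independent N(0, noise_sd^2) observation noise.
    Identical configs (including seed) give bit-identical output regardless
    of generation order, because every scan uses its own hashed substream.
    """
    truth = generate_latent_matrices(config)
    scans: list[ScanTimeSeries] = []
    for network, size in zip(config.network_names, config.network_sizes):
        for condition in config.conditions:
            for subject in config.subjects:
                for session in config.sessions:
                    target = truth.session_targets[(subject, session, condition, network)]
                    try:
                        L = np.linalg.cholesky(target)
                    except np.linalg.LinAlgError as exc:  # pragma: no cover
                        raise PositiveDefiniteProjectionError(
                            f"target for scan ({subject}, {session}, {condition}, "
                            f"{network}) is not positive definite"
                        ) from exc
                    rng = substream_rng(
                        config.seed, "scan", subject, session, condition, network
                    )
                    data = L @ rng.standard_normal((size, config.n_timepoints))
                    if config.noise_sd > 0:
                        data = data + rng.normal(
                            0.0, config.noise_sd, size=data.shape
                        )
                    scans.append(
                        ScanTimeSeries(
                            data=data,
                            tr_seconds=config.tr_seconds,
                            subject=subject,
                            session=session,
                            condition=condition,
                            network=network,
                        )
                    )
    return scans, truth


# ---------------------------------------------------------------------------
# On-disk cohort format: TSV per scan + JSON-lines manifest
# ---------------------------------------------------------------------------

def write_cohort(
    scans: list[ScanTimeSeries],
    out_dir: str | Path,
    truth: GroundTruth | None = None,
) -> Path:
    """Write scans as headerless node-by-time TSVs with a JSONL manifest.

    Returns the manifest path.  Ground truth, when given, is written as
    ``ground_truth.csv`` in long edge format.
    """
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for scan in scans:
            name = "_".join(scan.key()) + ".tsv"
            rel = f"scans/{name}"
            np.savetxt(out / rel, scan.data, delimiter="\t", fmt="%.10g")
            fh.write(json.dumps({
                "path": rel,
                "subject": scan.subject,
                "session": scan.session,
                "condition": scan.condition,
                "network": scan.network,
                "tr_seconds": scan.tr_seconds,
                "n_nodes": scan.n_nodes,
                "n_timepoints": scan.n_timepoints,
                "node_labels": scan.node_labels,
            }) + "\n")
    if truth is not None:
        truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    return manifest
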