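"""End-to-end pipeline: simulate -> preprocess -> connect -> threshold ->
metrics -> reliability -> permutation, with plain-text file interfaces.

Every stage writes a long-format CSV next to the run's effective config, so
a run directory is a complete, diff-able record: ``metrics.csv`` (one row
per scan and metric), ``connectivity.csv`` (one row per scan and edge),
``reliability.csv`` (one row per network x condition x metric cell),
``permutation.csv`` (one row per test) and ``best_condition.csv``.  Runs
are pure functions of (inputs, config, seed): re-running with an identical
config reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import compute_nfc, threshold_matrix
from .core import ScanTimeSeries, ValidationError, get_logger
from .metrics import ScanMetricRecord, scan_summary
from .permutation import permutation_to_frame, run_family
from .preprocess import preprocess_scan
from .reliability import (
    ReliabilityRecord,
    records_to_frame,
    reliability_table,
    reliability_to_frame,
)
from .synthetic import SimulationConfig, generate_cohort

logger = get_logger(__name__)

#: eMDN and extDMN are two names for the same network in the literature;
#: both are accepted and mapped to the canonical "eMDN".
NETWORK_ALIASES: dict[str, str] = {"extDMN": "eMDN"}


@dataclass
class NetworkDefinition:
    """A named node set with MNI millimetre coordinates."""

    name: str
    nodes: list[tuple[str, float, float, float]]

    def __post_init__(self) -> None:
        self.name = NETWORK_ALIASES.get(self.name, self.name)
        if not (2 <= len(self.nodes) <= 100):
            raise ValidationError(
                f"network {self.name}: node count must lie in [2, 100]"
            )
        labels = [n[0] for n in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"network {self.name}: duplicate node labels")

    @property
    def node_labels(self) -> list[str]:
        return [n[0] for n in self.nodes]


def read_network_definitions(path: str | Path) -> list[NetworkDefinition]:
    """Read a network definition CSV with columns name, label, x, y, z."""
    df = pd.read_csv(path)
    required = {"name", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"network definition CSV must have columns {sorted(required)}"
        )
    out = []
    for name, grp in df.groupby("name", sort=True):
        nodes = [(str(r.label), float(r.x), float(r.y), float(r.z))
                 for r in grp.itertuples()]
        out.append(NetworkDefinition(name=str(name), nodes=nodes))
    return out


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serialisable to YAML."""

    simulation: SimulationConfig | None = None
    manifest_path: str | None = None
    preprocess: bool = True
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    connectivity_kind: str = "correlation"
    threshold_tau: float = 0.1
    absolute_degree: bool = False
    baseline_condition: str = "RS"
    n_permutations: int = 5000
    run_permutations: bool = True
    seed: int = 0
    write_connectivity: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None and self.manifest_path is None:
            raise ValidationError("config needs a simulation block or a manifest path")
        if self.connectivity_kind not in ("correlation", "covariance"):
            raise ValidationError(f"unknown connectivity kind {self.connectivity_kind!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            for key in ("conditions", "network_sizes", "network_names"):
                if sim.get(key) is not None:
                    sim[key] = list(sim[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def read_scan_manifest(path: str | Path) -> list[ScanTimeSeries]:
    """Load scans from a JSON-lines manifest of TSV paths plus metadata.

    Malformed lines and dimension mismatches are reported with the line
    number / file name; an empty manifest gives an empty list with a warning.
    """
    path = Path(path)
    scans: list[ScanTimeSeries] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: malformed manifest line: {exc}"
                ) from exc
            try:
                tsv = path.parent / rec["path"]
                data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
                expected = rec.get("n_nodes")
                if expected is not None and data.shape[0] != expected:
                    raise ValidationError(
                        f"{tsv}: expected {expected} nodes for network "
                        f"{rec.get('network')}, found {data.shape[0]}"
                    )
                scans.append(ScanTimeSeries(
                    data=data,
                    tr_seconds=float(rec["tr_seconds"]),
                    subject=str(rec["subject"]),
                    session=str(rec["session"]),
                    condition=str(rec["condition"]),
                    network=str(rec["network"]),
                    node_labels=list(rec.get("node_labels") or []),
                ))
            except KeyError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: manifest record missing field {exc}"
                ) from exc
    if not scans:
        logger.warning("manifest %s contains no scans", path)
    return scans


def _check_complete_design(scans: list[ScanTimeSeries]) -> None:
    subjects = sorted({s.subject for s in scans})
    sessions = sorted({s.session for s in scans})
    conditions = sorted({s.condition for s in scans})
    networks = sorted({s.network for s in scans})
    have = {s.key() for s in scans}
    missing = [
        (su, se, co, ne)
        for su in subjects for se in sessions for co in conditions for ne in networks
        if (su, se, co, ne) not in have
    ]
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ValidationError(
            f"{len(missing)} missing scans in design, e.g. {shown}"
        )


def connectivity_to_frame(graphs) -> pd.DataFrame:
    """Long edge table of thresholded graphs: one row per retained edge."""
    rows = []
    for g in graphs:
        iu, ju = np.triu_indices(g.n_nodes, k=1)
        keep = g.support[iu, ju]
        for i, j in zip(iu[keep], ju[keep]):
            rows.append((g.subject, g.session, g.condition, g.network,
                         g.node_labels[i], g.node_labels[j],
                         float(g.weights[i, j])))
    return pd.DataFrame(
        rows, columns=["subject", "session", "condition", "network",
                       "node_i", "node_j", "weight"],
    )


def compute_scan_metrics(
    scans: list[ScanTimeSeries], config: PipelineConfig
) -> tuple[list[ScanMetricRecord], list]:
    """Preprocess (optionally), connect, threshold and summarise every scan."""
    records, graphs = [], []
    for scan in scans:
        if config.preprocess:
            scan = preprocess_scan(
                scan, low_hz=config.bandpass_low_hz, high_hz=config.bandpass_high_hz
            )
        C = compute_nfc(scan, kind=config.connectivity_kind)
        G = threshold_matrix(C, tau=config.threshold_tau)
        graphs.append(G)
        rec = scan_summary(G, absolute_degree=config.absolute_degree)
        records.append(rec)
        logger.debug(
            "scan %s: %d edges, %d disconnected pairs",
            scan.key(), rec.n_edges, rec.n_disconnected_pairs,
        )
    return records, graphs


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the stage CSVs plus the effective config.

    Returns the run directory.  A ``RUN_INCOMPLETE`` marker file exists
    while the run is in progress (and is left behind on failure).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "RUN_INCOMPLETE"
    marker.touch()

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = get_logger("netretest")
    root.addHandler(handler)
    try:
        config.to_yaml(out / "effective_config.yaml")
        if config.simulation is not None:
            scans, truth = generate_cohort(config.simulation)
            truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
        else:
            scans = read_scan_manifest(config.manifest_path)
        _check_complete_design(scans)
        logger.info("loaded %d scans", len(scans))

        records, graphs = compute_scan_metrics(scans, config)
        if config.write_connectivity:
            connectivity_to_frame(graphs).to_csv(out / "connectivity.csv", index=False)
        metrics_df = records_to_frame(records)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        logger.info("metrics table: %d rows (%d scans)", len(metrics_df), len(records))

        rel_records = reliability_table(records)
        rel_df = reliability_to_frame(rel_records)
        rel_df.to_csv(out / "reliability.csv", index=False)
        logger.info("reliability table: %d rows", len(rel_df))

        best = summarize_best_condition(rel_records)
        best["cells"].to_csv(out / "best_condition.csv", index=False)
        best["counts"].to_csv(out / "best_condition_counts.csv", index=False)

        if config.run_permutations:
            perm = run_family(
                records,
                baseline_condition=config.baseline_condition,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            perm_df = permutation_to_frame(perm)
            perm_df.to_csv(out / "permutation.csv", index=False)
            logger.info("permutation table: %d rows", len(perm_df))
    finally:
        root.removeHandler(handler)
        handler.close()
    marker.unlink()
    return out


def summarize_best_condition(
    reliability: list[ReliabilityRecord] | pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per (metric x network): the condition with the highest clamped ICC.

    Returns ``cells`` (one row per metric x network with the winning
    condition, its ICC, and a tie flag listing every co-winner) and
    ``counts`` (per metric: how many networks each condition wins; tied
    cells count for every tied condition).
    """
    df = (reliability if isinstance(reliability, pd.DataFrame)
          else reliability_to_frame(reliability))
    cells = []
    for (metric, network), grp in df.groupby(["metric", "network"], sort=True):
        best_icc = grp["icc"].max()
        winners = sorted(grp.loc[grp["icc"] == best_icc, "condition"])
        cells.append((metric, network, winners[0] if len(winners) == 1 else "",
                      float(best_icc), len(winners) > 1, ";".join(winners)))
    cells_df = pd.DataFrame(
        cells, columns=["metric", "network", "best_condition", "best_icc",
                        "tie", "winners"],
    )
    count_rows = []
    for metric, grp in cells_df.groupby("metric", sort=True):
        tally: dict[str, int] = {}
        for winners in grp["winners"]:
            for c in winners.split(";"):
                tally[c] = tally.get(c, 0) + 1
        for condition, n in sorted(tally.items()):
            count_rows.append((metric, condition, n))
    counts_df = pd.DataFrame(count_rows, columns=["metric", "condition", "n_networks"])
    return {"cells": cells_df, "counts": counts_df}
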