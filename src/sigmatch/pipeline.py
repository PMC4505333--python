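"""End-to-end orchestration: simulate/ingest → build PRLs → merge → distance → rank/cluster.

Two entry points:

* :func:`analyze_study` runs the whole method in memory on an expression
  matrix plus pairing manifest and returns the intermediate objects — the
  path used by tests and simulation sweeps.
* :func:`run_pipeline` is the on-disk variant: every stage reads only the
  artifacts written by the previous one and writes its own, so a run is
  resumable and auditable.  A run manifest records the configuration and a
  SHA-256 hash of every artifact; re-running with the same configuration and
  seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .distance import DEFAULT_SIGNATURE_SIZE, DistanceMatrix, distance_matrix
from .merge import MergeTrace, merge_condition_prls
from .prl import ProbeRankList, build_prl
from .report import cluster_distance_matrix, rank_perturbations
from .simulate import SimulationConfig, simulate_study

__all__ = ["RunConfig", "RunResult", "analyze_study", "run_pipeline"]

logger = logging.getLogger("sigmatch")


class PipelineValidationError(ValueError):
    """Configuration rejected before any stage ran."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Provide either ``simulation`` (a study is generated and written to the
    output directory) or both ``matrix_path`` and ``manifest_path``.
    ``query_label`` names the condition the final ranking is relative to.
    """

    out_dir: Path
    simulation: SimulationConfig | None = None
    matrix_path: Path | None = None
    manifest_path: Path | None = None
    signature_size: int = DEFAULT_SIGNATURE_SIZE
    query_label: str = "disease"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.signature_size < 1:
            raise PipelineValidationError("signature_size must be >= 1")
        has_sim = self.simulation is not None
        has_files = self.matrix_path is not None and self.manifest_path is not None
        if has_sim == has_files:
            raise PipelineValidationError(
                "provide either a simulation config or matrix+manifest paths"
            )
        if has_sim and 2 * self.signature_size > self.simulation.n_probes:
            raise PipelineValidationError(
                "2 x signature_size exceeds the simulated probe universe"
            )
        if has_files:
            for p in (self.matrix_path, self.manifest_path):
                if not Path(p).exists():
                    raise PipelineValidationError(f"input path does not exist: {p}")


@dataclass
class RunResult:
    """Artifacts and in-memory results of one pipeline run."""

    distances: DistanceMatrix
    ranking: pd.DataFrame
    merge_traces: dict[str, MergeTrace]
    artifacts: dict[str, Path]
    manifest: dict


def analyze_study(
    matrix: sio.ExpressionMatrix,
    manifest: sio.PairManifest,
    signature_size: int = DEFAULT_SIGNATURE_SIZE,
    query_label: str = "disease",
) -> RunResult:
    """Run the full method in memory and rank conditions against the query."""
    manifest.validate_against(matrix)
    if 2 * signature_size > matrix.shape[0]:
        raise PipelineValidationError("2 x signature_size exceeds the probe universe")

    condition_prls: dict[str, ProbeRankList] = {}
    traces: dict[str, MergeTrace] = {}
    for condition, entries in manifest.by_condition().items():
        prls = [
            build_prl(
                matrix.sample(e.experiment_id),
                matrix.sample(e.control_id),
                matrix.probe_ids,
            )
            for e in entries
        ]
        condition_prls[condition], traces[condition] = merge_condition_prls(prls)

    dm = distance_matrix(condition_prls, n=signature_size)
    ranking = rank_perturbations(dm, query_label)
    return RunResult(
        distances=dm, ranking=ranking, merge_traces=traces, artifacts={}, manifest={}
    )


# --------------------------------------------------------------------------- #
# on-disk pipeline
# --------------------------------------------------------------------------- #

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_trace(trace: MergeTrace, path: Path) -> None:
    rows = [
        {
            "step": i + 1,
            "left": "+".join(map(str, s.left)),
            "right": "+".join(map(str, s.right)),
            "footrule_distance": s.distance,
        }
        for i, s in enumerate(trace.steps)
    ]
    pd.DataFrame(rows, columns=["step", "left", "right", "footrule_distance"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage, writing all intermediate artifacts to ``out_dir``."""
    logging.basicConfig(level=config.log_level, format="%(asctime)s %(name)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def log(stage: str, msg: str) -> None:
        logger.info("[%s] %s", stage, msg)

    # stage 0: obtain inputs -------------------------------------------------
    if config.simulation is not None:
        log("simulate", f"generating synthetic study (seed={config.simulation.seed})")
        matrix, pair_manifest, ground_truth = simulate_study(config.simulation)
        artifacts["matrix"] = out / "matrix.tsv"
        matrix.write_tsv(artifacts["matrix"])
        artifacts["pairs"] = out / "pairs.tsv"
        sio.write_pair_manifest(pair_manifest, artifacts["pairs"])
        artifacts["ground_truth"] = out / "ground_truth.json"
        artifacts["ground_truth"].write_text(
            json.dumps(ground_truth, indent=1, sort_keys=True) + "\n"
        )
    else:
        artifacts["matrix"] = Path(config.matrix_path)
        artifacts["pairs"] = Path(config.manifest_path)

    # stage 1: build one PRL per pair (reads only on-disk inputs) ------------
    matrix = sio.read_expression_matrix(artifacts["matrix"])
    pair_manifest = sio.read_pair_manifest(artifacts["pairs"])
    pair_manifest.validate_against(matrix)
    if 2 * config.signature_size > matrix.shape[0]:
        raise PipelineValidationError("2 x signature_size exceeds the probe universe")

    prl_dir = out / "prls"
    prl_dir.mkdir(exist_ok=True)
    log("build-prl", f"building {len(pair_manifest)} rank lists")
    for e in pair_manifest.entries:
        prl = build_prl(
            matrix.sample(e.experiment_id), matrix.sample(e.control_id), matrix.probe_ids
        )
        sio.write_prl(prl, prl_dir / f"{e.condition}__{e.dataset}__{e.experiment_id}.prl.tsv")

    # stage 2: merge replicates per condition --------------------------------
    merged_dir = out / "merged"
    merged_dir.mkdir(exist_ok=True)
    traces: dict[str, MergeTrace] = {}
    condition_prls: dict[str, ProbeRankList] = {}
    for condition, entries in pair_manifest.by_condition().items():
        prls = [
            sio.read_prl(prl_dir / f"{e.condition}__{e.dataset}__{e.experiment_id}.prl.tsv")
            for e in entries
        ]
        merged, trace = merge_condition_prls(prls)
        condition_prls[condition] = merged
        traces[condition] = trace
        sio.write_prl(merged, merged_dir / f"{condition}.prl.tsv")
        _write_trace(trace, merged_dir / f"{condition}.merge_trace.tsv")
    log("merge", f"merged {len(pair_manifest)} rank lists into {len(condition_prls)} conditions")

    # stage 3: distance matrix ----------------------------------------------
    dm = distance_matrix(condition_prls, n=config.signature_size)
    artifacts["distances"] = out / "distances.tsv"
    sio.write_distance_matrix(dm, artifacts["distances"])
    log("distance", f"{len(dm.labels)} x {len(dm.labels)} distance matrix written")

    # stage 4: ranking + clustering (reads the on-disk matrix back) ----------
    dm = sio.read_distance_matrix(artifacts["distances"])
    ranking = rank_perturbations(dm, config.query_label)
    artifacts["ranking"] = out / "ranking.tsv"
    ranking.to_csv(artifacts["ranking"], sep="\t", index=False, float_format="%.12g")

    linkage, leaf_order = cluster_distance_matrix(dm)
    artifacts["linkage"] = out / "linkage.tsv"
    pd.DataFrame(
        linkage, columns=["member_a", "member_b", "height", "size"]
    ).to_csv(artifacts["linkage"], sep="\t", index=False, float_format="%.12g")
    artifacts["leaf_order"] = out / "leaf_order.tsv"
    pd.Series(leaf_order, name="condition").to_csv(
        artifacts["leaf_order"], sep="\t", index=False
    )
    log("rank", f"top condition: {ranking.iloc[0]['condition']}")

    # run manifest: config + content hashes (no timestamps, for reproducibility)
    run_manifest = {
        "config": {
            "signature_size": config.signature_size,
            "query_label": config.query_label,
            "simulation": (
                config.simulation.to_dict() if config.simulation is not None else None
            ),
            "matrix_path": str(config.matrix_path) if config.matrix_path else None,
            "manifest_path": str(config.manifest_path) if config.manifest_path else None,
        },
        "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(run_manifest, indent=1, sort_keys=True) + "\n")
    artifacts["run_manifest"] = manifest_path

    return RunResult(
        distances=dm,
        ranking=ranking,
        merge_traces=traces,
        artifacts=artifacts,
        manifest=run_manifest,
    )
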