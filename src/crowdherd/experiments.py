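"""Run orchestration: manifests, logging artefacts, and the squeeze-through
comparative scan.

A "run" here is one evolutionary simulation executed to completion with
its per-generation metrics streamed to CSV, genotype archives written as
JSON, and a manifest tying config, seed and artefact paths together so
the run can be reproduced byte-exactly or resumed from a checkpoint.

The comparative scan sweeps the squeeze-through probability ``p_transit``
over a value grid with several replicate runs per value and tabulates the
final evolved state of each replicate (late-run means of the neighbour
and mobility scores), the raw material for violin-style summaries of the
two evolutionarily stable regimes (collective motion vs stationary
herds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evolution import (
    EvolutionResult,
    SimConfig,
    records_to_frame,
    run_evolution,
    run_generation,
)
from .genotype import archive_to_json

__all__ = [
    "RunManifest",
    "run_with_manifest",
    "resume_run",
    "scan_ptransit",
    "export_snapshots",
]


@dataclass
class RunManifest:
    """Reproducibility record of one run: config snapshot, seed, artefact
    paths and completion status.  The config in the manifest reproduces
    the run byte-exactly."""

    config: dict
    seed: int
    metrics_path: str
    archive_paths: dict[int, str] = field(default_factory=dict)
    checkpoint_path: str | None = None
    status: str = "pending"

    def to_json(self) -> str:
        doc = {
            "config": self.config,
            "seed": self.seed,
            "metrics_path": self.metrics_path,
            "archive_paths": {str(g): p for g, p in self.archive_paths.items()},
            "checkpoint_path": self.checkpoint_path,
            "status": self.status,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        doc = json.loads(text)
        return cls(
            config=doc["config"],
            seed=doc["seed"],
            metrics_path=doc["metrics_path"],
            archive_paths={int(g): p for g, p in doc["archive_paths"].items()},
            checkpoint_path=doc.get("checkpoint_path"),
            status=doc["status"],
        )


def run_with_manifest(
    config: SimConfig,
    outdir: str | Path,
    *,
    archive_every: int = 20,
    checkpoint_every: int = 100,
    log: Callable[[str], None] | None = None,
    resume_from: str | Path | None = None,
) -> tuple[RunManifest, EvolutionResult]:
    """Execute a run, writing metrics CSV, archives, checkpoint and manifest.

    Artefacts under ``outdir``: ``metrics.csv`` (one row per generation),
    ``archives/generation_<g>.json`` genotype archives, ``checkpoint.json``
    (rolling), and ``manifest.json``.  ``log``, when given, receives one
    progress line per generation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    archive_dir = outdir / "archives"
    archive_dir.mkdir(exist_ok=True)
    metrics_path = outdir / "metrics.csv"
    checkpoint_path = outdir / "checkpoint.json"

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        metrics_path=str(metrics_path),
        checkpoint_path=str(checkpoint_path),
        status="running",
    )
    (outdir / "manifest.json").write_text(manifest.to_json())

    def _progress(rec):
        if log is not None:
            log(
                f"generation {rec.generation:5d}  "
                f"neighbour {rec.mean_neighbour_score:6.3f}  "
                f"mobility {rec.mean_mobility_score:6.3f}"
            )

    result = run_evolution(
        config,
        archive_every=archive_every,
        on_generation=_progress,
        checkpoint_path=checkpoint_path,
        checkpoint_every=checkpoint_every,
        resume_from=resume_from,
    )
    for g, weights in sorted(result.archives.items()):
        path = archive_dir / f"generation_{g:05d}.json"
        path.write_text(archive_to_json(g, weights))
        manifest.archive_paths[g] = str(path)
    records_to_frame(result.records).to_csv(metrics_path, index=False)
    manifest.status = "completed"
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest, result


def resume_run(outdir: str | Path, **kwargs) -> tuple[RunManifest, EvolutionResult]:
    """Continue an interrupted run from its last checkpoint."""
    outdir = Path(outdir)
    manifest = RunManifest.from_json((outdir / "manifest.json").read_text())
    config = SimConfig.from_dict(manifest.config)
    return run_with_manifest(
        config, outdir, resume_from=manifest.checkpoint_path, **kwargs
    )


def scan_ptransit(
    values: Sequence[float],
    replicates: int,
    base_config: SimConfig,
    *,
    final_window: int = 100,
    log: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Comparative sweep of the squeeze-through probability.

    For every value in ``values`` (the reference grid is 0.0 to 1.0 in
    steps of 0.1) and every replicate, one evolutionary run is executed
    with an independent seed derived from ``base_config.seed``; the final
    evolved state is summarised by the mean neighbour and mobility scores
    averaged over the last ``final_window`` generations.  The returned
    table has ``len(values) * replicates`` rows.
    """
    values = [float(v) for v in values]
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ValueError("p_transit values must lie in [0, 1]")
    seeds = np.random.SeedSequence(base_config.seed).generate_state(
        len(values) * replicates
    ) % (2**31)
    rows = []
    idx = 0
    for v in values:
        for rep in range(replicates):
            seed = int(seeds[idx])
            idx += 1
            cfg = base_config.with_(p_transit=v, seed=seed)
            result = run_evolution(cfg, archive_every=0, epoch_generations=())
            frame = records_to_frame(result.records)
            tail = frame.tail(final_window)
            rows.append(
                {
                    "p_transit": v,
                    "replicate": rep,
                    "seed": seed,
                    "final_neighbour_score": tail["mean_neighbour_score"].mean(),
                    "final_mobility_score": tail["mean_mobility_score"].mean(),
                }
            )
            if log is not None:
                log(
                    f"p_transit {v:.1f} replicate {rep}: "
                    f"neighbour {rows[-1]['final_neighbour_score']:.3f} "
                    f"mobility {rows[-1]['final_mobility_score']:.3f}"
                )
    return pd.DataFrame(rows)


def export_snapshots(
    config: SimConfig,
    genotypes,
    generation: int,
    path: str | Path,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one generation and export per-step agent positions.

    Writes (and returns) a CSV table with columns ``generation, step,
    agent_id, x, y`` (0-based; x = column, y = row), the documented
    snapshot format for trajectory visualisation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = run_generation(
        config, genotypes, rng, generation=generation, collect=True
    )
    T, n, _ = out.trajectories.shape
    frame = pd.DataFrame(
        {
            "generation": np.full(T * n, generation, dtype=np.int64),
            "step": np.repeat(np.arange(1, T + 1), n),
            "agent_id": np.tile(np.arange(n), T),
            "x": out.trajectories[:, :, 0].ravel(),
            "y": out.trajectories[:, :, 1].ravel(),
        }
    )
    frame.to_csv(path, index=False)
    return frame
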