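"""End-to-end screen orchestration: load -> stage 1 per target -> stage 2
-> summary, with a reproducibility manifest.

All inputs are loaded and validated and the full result computed before
any output file is written, so a failing stage never leaves a partial hit
list behind.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .consensus import (
    ConsensusHitList,
    ConsensusParams,
    ScreenSummary,
    load_score_table,
    stage_one_consensus,
    stage_two_consensus,
    summarize_screen,
)

__all__ = ["RunConfig", "run_screen"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one consensus-screen run.

    ``score_paths`` maps target id -> delimited score-table path.
    ``library_size`` defaults to the compound count of the first table.
    """

    score_paths: Mapping[str, str]
    q_model: float = 0.10
    m_min: int = 5
    q_target: float = 0.25
    t_min: int = 3
    library_size: int | None = None
    out_dir: str | None = None
    seed: int = 0

    def params(self) -> ConsensusParams:
        return ConsensusParams(
            q_model=self.q_model, m_min=self.m_min,
            q_target=self.q_target, t_min=self.t_min,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["score_paths"] = dict(self.score_paths)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_screen(
    config: RunConfig,
) -> tuple[ScreenSummary, ConsensusHitList, dict]:
    """Execute the two-stage consensus screen described by ``config``.

    Returns (summary, consensus hit list, manifest); when ``out_dir`` is
    set, also writes per-target stage-1 lists, the consensus list, a
    key-value summary and a YAML manifest with input digests.
    """
    if not config.score_paths:
        raise ValueError("no score tables configured")
    params = config.params()

    tables = {
        target: load_score_table(path, target_id=target)
        for target, path in sorted(config.score_paths.items())
    }
    n_models = {t.n_models for t in tables.values()}
    if len(n_models) != 1:
        raise ValueError(f"targets disagree on model count: {sorted(n_models)}")

    stage1 = [stage_one_consensus(t, params) for t in tables.values()]
    final = stage_two_consensus(stage1, params)
    library_size = config.library_size or next(iter(tables.values())).n_compounds
    summary = summarize_screen(library_size, n_models.pop(), stage1, final)

    manifest = {
        "tool": "kinscreen",
        "version": __version__,
        "params": {
            "q_model": params.q_model, "m_min": params.m_min,
            "q_target": params.q_target, "t_min": params.t_min,
        },
        "library_size": summary.library_size,
        "inputs": {
            target: {"path": str(path), "sha256": _sha256(path)}
            for target, path in sorted(config.score_paths.items())
        },
        "stage1_counts": dict(summary.stage1_counts),
        "final_count": summary.final_count,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for hl in stage1:
            hl.to_frame().to_csv(out / f"stage1_{hl.target_id}.csv", index=False)
        final.to_frame().to_csv(out / "consensus_hits.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "library_size": summary.library_size,
                    "n_targets": summary.n_targets,
                    "n_models_per_target": summary.n_models_per_target,
                    "stage1_counts": dict(summary.stage1_counts),
                    "final_count": summary.final_count,
                    "final_fraction_percent": summary.final_fraction_percent,
                    "total_docking_runs": summary.total_docking_runs,
                },
                indent=2,
            )
        )
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    return summary, final, manifest
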