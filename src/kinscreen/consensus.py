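"""Two-stage multi-model / multi-target consensus ranking of docking scores.

Ensemble docking screens score every compound of a library against several
receptor models per kinase target (lower score = better pose, the usual
docking-energy convention).  Single-model rankings are noisy; the consensus
filter implemented here combines them in two stages:

Stage 1 (per target)
    A compound survives for a target if its score lies in the best
    ``q_model`` fraction (default top 10%) of at least ``m_min`` of that
    target's ``M`` ensemble models (default 5 of 10).  Each survivor is
    represented by its best (minimum) score over the models in which it
    qualified, and the survivors form a ranked per-target hit list.

Stage 2 (across targets)
    A compound supports a target if it sits in the best ``q_target``
    fraction (default top 25%) of that target's stage-1 hit list.  A
    compound enters the final consensus list if it supports at least
    ``t_min`` targets (default 3 of 4).  The final ordering is by the mean
    of its per-target hit-list percentiles over the targets it supports,
    with ties broken by broader target support and then by compound id.

All ranking is deterministic: tied scores share the minimum rank of the
tied block, and every ordering falls back to lexicographic compound id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DockingScoreTable",
    "ConsensusParams",
    "HitEntry",
    "TargetHitList",
    "ConsensusEntry",
    "ConsensusHitList",
    "ScreenSummary",
    "load_score_table",
    "save_score_table",
    "per_model_percentiles",
    "stage_one_consensus",
    "stage_two_consensus",
    "consensus_rank_of",
    "summarize_screen",
]

ABSENT_MARKER = "NA"


@dataclass(frozen=True)
class DockingScoreTable:
    """Per-target matrix of docking scores, compounds x ensemble models.

    ``scores`` is an ``(n, M)`` float array with ``NaN`` marking a
    compound/model pair that was never docked.  Lower scores are better
    unless ``lower_is_better`` is flipped.
    """

    target_id: str
    compound_ids: tuple[str, ...]
    model_ids: tuple[str, ...]
    scores: np.ndarray
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        n, m = len(self.compound_ids), len(self.model_ids)
        if n < 1 or m < 1:
            raise ValueError("score table needs at least one compound and one model")
        if len(set(self.compound_ids)) != n:
            dupes = _duplicates(self.compound_ids)
            raise ValueError(f"duplicate compound id(s): {sorted(dupes)}")
        if len(set(self.model_ids)) != m:
            raise ValueError(f"duplicate model id(s): {sorted(_duplicates(self.model_ids))}")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (n, m):
            raise ValueError(f"scores shape {scores.shape} != ({n}, {m})")
        if np.isinf(scores).any():
            raise ValueError("scores must be finite or absent (NaN)")
        object.__setattr__(self, "scores", scores)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.compound_ids), columns=list(self.model_ids)
        )


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the two-stage consensus filter.

    Defaults are the screen's published operating point: top 10% in at
    least 5 of 10 models per target, then top 25% of the hit list in at
    least 3 of 4 targets.
    """

    q_model: float = 0.10
    m_min: int = 5
    q_target: float = 0.25
    t_min: int = 3

    def __post_init__(self) -> None:
        for name, q in (("q_model", self.q_model), ("q_target", self.q_target)):
            if not (0.0 < q <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {q}")
        for name, k in (("m_min", self.m_min), ("t_min", self.t_min)):
            if k < 1:
                raise ValueError(f"{name} must be >= 1, got {k}")


@dataclass(frozen=True)
class HitEntry:
    compound_id: str
    representative_score: float
    n_qualifying_models: int
    percentile_rank: float


@dataclass(frozen=True)
class TargetHitList:
    """Stage-1 survivors of one target, ascending by representative score."""

    target_id: str
    entries: tuple[HitEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def compound_ids(self) -> tuple[str, ...]:
        return tuple(e.compound_id for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.compound_id, e.representative_score, e.n_qualifying_models, e.percentile_rank)
                for e in self.entries
            ],
            columns=["compound_id", "representative_score", "n_qualifying_models", "percentile_rank"],
        )


@dataclass(frozen=True)
class ConsensusEntry:
    compound_id: str
    n_supporting_targets: int
    consensus_rank: int
    per_target_percentiles: Mapping[str, float]  # only targets where the compound appears


@dataclass(frozen=True)
class ConsensusHitList:
    entries: tuple[ConsensusEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def compound_ids(self) -> tuple[str, ...]:
        return tuple(e.compound_id for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            mean_pct = float(np.mean(list(e.per_target_percentiles.values())))
            rows.append((e.consensus_rank, e.compound_id, e.n_supporting_targets, mean_pct))
        return pd.DataFrame(
            rows, columns=["consensus_rank", "compound_id", "n_supporting_targets", "mean_percentile"]
        )


@dataclass(frozen=True)
class ScreenSummary:
    library_size: int
    n_targets: int
    n_models_per_target: int
    stage1_counts: Mapping[str, int]
    final_count: int
    final_fraction_percent: float
    total_docking_runs: int


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        (dupes if x in seen else seen).add(x)
    return dupes


def load_score_table(source: str | Path | IO[str], target_id: str) -> DockingScoreTable:
    """Read a delimited score table (comma or tab, auto-detected).

    Expected layout: header row ``compound_id,<model_1>,...,<model_M>``;
    one row per compound; absent cells marked ``NA``.
    """
    df = pd.read_csv(
        source,
        sep=None,
        engine="python",
        na_values=[ABSENT_MARKER],
        keep_default_na=False,
        dtype={0: str},
    )
    if df.shape[1] < 2:
        raise ValueError("score table needs a compound-id column and at least one model column")
    compound_ids = df.iloc[:, 0].astype(str).tolist()
    dupes = _duplicates(compound_ids)
    if dupes:
        raise ValueError(f"duplicate compound id(s) in {target_id!r}: {sorted(dupes)}")
    model_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric score {raw.iat[i, j]!r} at compound {compound_ids[i]!r}, "
            f"model {model_ids[j]!r}"
        )
    return DockingScoreTable(
        target_id=target_id,
        compound_ids=tuple(compound_ids),
        model_ids=tuple(model_ids),
        scores=numeric.to_numpy(dtype=float),
    )


def save_score_table(table: DockingScoreTable, dest: str | Path | IO[str]) -> None:
    df = table.to_frame()
    df.index.name = "compound_id"
    df.to_csv(dest, na_rep=ABSENT_MARKER)


def per_model_percentiles(table: DockingScoreTable) -> pd.DataFrame:
    """Percentile of each compound within each model column.

    Percentile = (1-based ascending min-rank among the column's non-absent
    scores) / (count of non-absent scores); tied scores share the minimum
    rank of the tied block; absent cells stay absent (NaN).
    """
    scores = table.scores if table.lower_is_better else -table.scores
    out = np.full_like(scores, np.nan, dtype=float)
    for j, model_id in enumerate(table.model_ids):
        col = scores[:, j]
        mask = ~np.isnan(col)
        count = int(mask.sum())
        if count == 0:
            raise ValueError(f"model column {model_id!r} is entirely absent")
        ranks = rankdata(col[mask], method="min")
        out[mask, j] = ranks / count
    return pd.DataFrame(out, index=list(table.compound_ids), columns=list(table.model_ids))


def stage_one_consensus(table: DockingScoreTable, params: ConsensusParams) -> TargetHitList:
    """Per-target consensus: keep compounds in the top ``q_model`` fraction
    of at least ``m_min`` models, represented by their best qualifying score."""
    if params.m_min > table.n_models:
        raise ValueError(
            f"m_min={params.m_min} exceeds the {table.n_models} models of {table.target_id!r}"
        )
    pct = per_model_percentiles(table).to_numpy()
    qualifies = pct <= params.q_model  # NaN compares False
    n_qual = qualifies.sum(axis=1)
    keep = n_qual >= params.m_min
    if not keep.any():
        return TargetHitList(target_id=table.target_id, entries=())

    oriented = table.scores if table.lower_is_better else -table.scores
    idx = np.flatnonzero(keep)
    rep = np.where(qualifies[idx], oriented[idx], np.nan)
    rep_score = np.full(table.n_compounds, np.nan)
    rep_score[idx] = np.nanmin(rep, axis=1)  # kept rows qualify somewhere
    order = sorted(idx, key=lambda i: (rep_score[i], table.compound_ids[i]))
    reps = np.array([rep_score[i] for i in order])
    k = len(order)
    list_ranks = rankdata(reps, method="min") / k
    entries = tuple(
        HitEntry(
            compound_id=table.compound_ids[i],
            representative_score=float(
                rep_score[i] if table.lower_is_better else -rep_score[i]
            ),
            n_qualifying_models=int(n_qual[i]),
            percentile_rank=float(pr),
        )
        for i, pr in zip(order, list_ranks)
    )
    return TargetHitList(target_id=table.target_id, entries=entries)


def stage_two_consensus(
    hitlists: Sequence[TargetHitList], params: ConsensusParams
) -> ConsensusHitList:
    """Cross-target consensus over the stage-1 hit lists.

    A compound supports a target if it appears in that target's stage-1
    list with hit-list percentile <= ``q_target``; it enters the final list
    when supported by at least ``t_min`` targets.  Ordered by ascending
    mean supporting-target percentile, ties by larger support count, then
    compound id; ranks are dense 1..K.
    """
    target_ids = [hl.target_id for hl in hitlists]
    dupes = _duplicates(target_ids)
    if dupes:
        raise ValueError(f"duplicate target id(s): {sorted(dupes)}")
    if len(hitlists) < params.t_min:
        raise ValueError(
            f"t_min={params.t_min} exceeds the {len(hitlists)} hit lists supplied"
        )

    percentiles: dict[str, dict[str, float]] = {}
    support: dict[str, list[float]] = {}
    for hl in hitlists:
        for e in hl.entries:
            percentiles.setdefault(e.compound_id, {})[hl.target_id] = e.percentile_rank
            if e.percentile_rank <= params.q_target:
                support.setdefault(e.compound_id, []).append(e.percentile_rank)

    selected = [cid for cid, pcts in support.items() if len(pcts) >= params.t_min]
    selected.sort(
        key=lambda cid: (float(np.mean(support[cid])), -len(support[cid]), cid)
    )
    entries = tuple(
        ConsensusEntry(
            compound_id=cid,
            n_supporting_targets=len(support[cid]),
            consensus_rank=rank,
            per_target_percentiles=dict(percentiles[cid]),
        )
        for rank, cid in enumerate(selected, start=1)
    )
    return ConsensusHitList(entries=entries)


def consensus_rank_of(hitlist: ConsensusHitList, compound_id: str) -> int | None:
    """Dense 1-based consensus rank of a compound, or None if absent."""
    for e in hitlist.entries:
        if e.compound_id == compound_id:
            return e.consensus_rank
    return None


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def summarize_screen(
    library_size: int,
    n_models_per_target: int,
    stage1: Sequence[TargetHitList],
    final: ConsensusHitList,
) -> ScreenSummary:
    """Screen bookkeeping: per-stage counts, the final library fraction (to
    3 significant figures, in percent) and the total number of docking runs."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if library_size < len(final):
        raise ValueError("final hit list larger than the library")
    n_targets = len(stage1)
    return ScreenSummary(
        library_size=library_size,
        n_targets=n_targets,
        n_models_per_target=n_models_per_target,
        stage1_counts={hl.target_id: len(hl) for hl in stage1},
        final_count=len(final),
        final_fraction_percent=_round_sig(100.0 * len(final) / library_size, 3),
        total_docking_runs=library_size * n_targets * n_models_per_target,
    )
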