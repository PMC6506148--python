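"""Retrospective screening power: ROC-AUC and enrichment factor.

Given docking scores for a benchmark of known actives and inactives
(lower score = better), the ROC area under the curve is computed in its
rank (Mann-Whitney) formulation — the probability that a randomly drawn
active outscores a randomly drawn inactive, ties counted one half — and
reported in percent.  The enrichment factor EF(f) is the concentration of
actives in the best fraction f of the ranked list relative to random
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ScoredCompound", "LabelledScores", "load_labelled_scores", "roc_auc", "enrichment_factor"]


@dataclass(frozen=True)
class ScoredCompound:
    compound_id: str
    score: float
    active: bool


@dataclass(frozen=True)
class LabelledScores:
    entries: tuple[ScoredCompound, ...]

    def __post_init__(self) -> None:
        if any(not math.isfinite(e.score) for e in self.entries):
            raise ValueError("scores must be finite")

    @property
    def n_actives(self) -> int:
        return sum(e.active for e in self.entries)

    @property
    def n_inactives(self) -> int:
        return len(self.entries) - self.n_actives

    def __len__(self) -> int:
        return len(self.entries)


def load_labelled_scores(source: str | Path | IO[str]) -> LabelledScores:
    """Read ``compound_id,score,label`` with labels ``active``/``inactive``."""
    df = pd.read_csv(source, sep=None, engine="python")
    labels = df.iloc[:, 2].astype(str).str.strip().str.lower()
    bad = set(labels) - {"active", "inactive"}
    if bad:
        raise ValueError(f"labels must be active/inactive, got {sorted(bad)}")
    return LabelledScores(
        entries=tuple(
            ScoredCompound(str(c), float(s), lab == "active")
            for c, s, lab in zip(df.iloc[:, 0], df.iloc[:, 1], labels)
        )
    )


def roc_auc(data: LabelledScores) -> float:
    """ROC-AUC in percent under the lower-is-better convention.

    AUC = 100 x [#(active, inactive) pairs with active score strictly
    lower + half the tied pairs] / (n_active x n_inactive), computed from
    average ranks.
    """
    n_a, n_i = data.n_actives, data.n_inactives
    if n_a == 0 or n_i == 0:
        raise ValueError("AUC needs at least one active and one inactive")
    scores = np.array([e.score for e in data.entries])
    active = np.array([e.active for e in data.entries])
    ranks = rankdata(scores, method="average")  # ascending: best = rank 1
    # pairs where the active scores WORSE than an inactive (ties half):
    worse = ranks[active].sum() - n_a * (n_a + 1) / 2
    return float(100.0 * (1.0 - worse / (n_a * n_i)))


def enrichment_factor(data: LabelledScores, fraction: float) -> float:
    """EF(f) = (active rate in the best ceil(f*n) compounds) / (overall
    active rate).  Score ties at the cutoff are resolved by compound id."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n = len(data)
    n_a = data.n_actives
    if n_a == 0 or data.n_inactives == 0:
        raise ValueError("EF needs at least one active and one inactive")
    cutoff = math.ceil(fraction * n)
    if cutoff < 1:
        raise ValueError("fraction*n must be >= 1")
    top = sorted(data.entries, key=lambda e: (e.score, e.compound_id))[:cutoff]
    hits = sum(e.active for e in top)
    return float((hits / cutoff) / (n_a / n))
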