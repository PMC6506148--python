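"""Statistics for whole-animal rescue-from-lethality assays.

The readout of the fly assay is eclosion: of the larvae that pupariated
(P empty pupal cases) how many eclosed to adulthood (A adults).  Viability
is 100*A/P per replicate vial.  A compound "rescues" the otherwise-lethal
transgenic genotype when treated viability exceeds the vehicle control in
a one-sided two-sample Student's t-test (pooled variance, alpha = 0.05).
Compound toxicity is gated on the wild-type flies raised in the same
vials: every control replicate must stay above 90% viability.  A drug
pair is called synergistic when the combination beats the sum of the
single-agent means and is significantly better than the better single
agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayRecord",
    "RescueResult",
    "load_assay_table",
    "viability",
    "viability_by_condition",
    "rescue_test",
    "toxicity_check",
    "synergy_call",
]


@dataclass(frozen=True)
class AssayRecord:
    """One replicate vial: P empty pupal cases, A surviving adults."""

    condition: str
    genotype: str
    replicate: int
    P: int
    A: int
    dose_uM: float | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.P < 0 or self.A < 0 or self.A > self.P:
            raise ValueError(
                f"counts must satisfy 0 <= A <= P, got A={self.A}, P={self.P}"
            )


@dataclass(frozen=True)
class RescueResult:
    condition: str
    control: str
    mean_viability: float
    sd: float
    n_replicates: int
    t_statistic: float
    p_one_sided: float
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False


def load_assay_table(source: str | Path | IO[str]) -> list[AssayRecord]:
    """Read ``condition,genotype,dose_uM,replicate,P,A`` delimited text."""
    df = pd.read_csv(source, sep=None, engine="python")
    needed = {"condition", "genotype", "replicate", "P", "A"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing column(s): {sorted(missing)}")
    return [
        AssayRecord(
            condition=str(row.condition),
            genotype=str(row.genotype),
            replicate=int(row.replicate),
            P=int(row.P),
            A=int(row.A),
            dose_uM=float(row.dose_uM) if "dose_uM" in df.columns and not pd.isna(row.dose_uM) else None,
        )
        for row in df.itertuples()
    ]


def viability(record: AssayRecord) -> float:
    """Percent viability 100*A/P; undefined (error) when no pupal cases."""
    if record.P == 0:
        raise ValueError(
            f"no eclosion events for {record.condition!r} replicate {record.replicate}"
        )
    return 100.0 * record.A / record.P


def viability_by_condition(
    records: Sequence[AssayRecord], genotype: str | None = None
) -> dict[str, list[float]]:
    """Replicate viabilities grouped by condition, replicate order preserved."""
    out: dict[str, list[float]] = {}
    for rec in sorted(records, key=lambda r: r.replicate):
        if genotype is not None and rec.genotype != genotype:
            continue
        out.setdefault(rec.condition, []).append(viability(rec))
    return out


def rescue_test(
    treated: Sequence[float],
    control: Sequence[float],
    condition: str = "treated",
    control_label: str = "vehicle",
    alpha: float = 0.05,
    welch: bool = False,
) -> RescueResult:
    """One-sided two-sample t-test of treated > control on replicate
    viability percentages.

    Classical pooled-variance Student's t by default (df = n1+n2-2); Welch
    behind a flag.  Zero pooled variance is degenerate: equal means give
    p = 0.5, a treated excess gives p -> 0 (flagged), a deficit p -> 1.
    """
    t_arr = np.asarray(treated, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if len(t_arr) < 2 or len(c_arr) < 2:
        raise ValueError("need >= 2 replicates in each arm")
    mean_t = float(t_arr.mean())
    degenerate = False
    if np.ptp(t_arr) == 0 and np.ptp(c_arr) == 0:
        diff = mean_t - float(c_arr.mean())
        if diff == 0:
            t_stat, p = 0.0, 0.5
        else:
            t_stat = math.copysign(math.inf, diff)
            p = 0.0 if diff > 0 else 1.0
            degenerate = True
    else:
        res = stats.ttest_ind(t_arr, c_arr, equal_var=not welch, alternative="greater")
        t_stat, p = float(res.statistic), float(res.pvalue)
    return RescueResult(
        condition=condition,
        control=control_label,
        mean_viability=mean_t,
        sd=float(t_arr.std(ddof=1)),
        n_replicates=len(t_arr),
        t_statistic=t_stat,
        p_one_sided=p,
        significant=p < alpha,
        alpha=alpha,
        degenerate=degenerate,
    )


def toxicity_check(
    control_records: Sequence[AssayRecord],
    threshold: float = 90.0,
    conditions: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Per-condition toxicity gate on wild-type (control-genotype) vials.

    A condition passes iff every replicate viability is strictly above
    ``threshold`` percent.  Asking about a condition with no control
    records is an error.
    """
    if not control_records:
        raise ValueError("no control records supplied")
    by_cond = viability_by_condition(control_records)
    wanted = list(conditions) if conditions is not None else list(by_cond)
    out = {}
    for cond in wanted:
        if cond not in by_cond:
            raise ValueError(f"no control records for condition {cond!r}")
        out[cond] = all(v > threshold for v in by_cond[cond])
    return out


def _summary_t_greater(a: RescueResult, b: RescueResult) -> float:
    """One-sided pooled-t p-value for mean(a) > mean(b) from summary stats."""
    if a.sd == 0 and b.sd == 0:
        diff = a.mean_viability - b.mean_viability
        return 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
    res = stats.ttest_ind_from_stats(
        a.mean_viability, a.sd, a.n_replicates,
        b.mean_viability, b.sd, b.n_replicates,
        equal_var=True, alternative="greater",
    )
    return float(res.pvalue)


def synergy_call(
    combo: RescueResult,
    single_a: RescueResult,
    single_b: RescueResult,
    alpha: float = 0.05,
) -> str:
    """Classify a two-drug combination as ``synergistic`` or
    ``non-synergistic``.

    Synergistic iff the combo mean strictly exceeds the sum of the single
    means AND the combo is significantly better (one-sided pooled t) than
    the better single arm.  All three arms must reference the same
    vehicle control.
    """
    refs = {combo.control, single_a.control, single_b.control}
    if len(refs) != 1:
        raise ValueError(f"arms reference different controls: {sorted(refs)}")
    additive = single_a.mean_viability + single_b.mean_viability
    if combo.mean_viability <= additive:
        return "non-synergistic"
    better = max((single_a, single_b), key=lambda r: r.mean_viability)
    p = _summary_t_greater(combo, better)
    return "synergistic" if p < alpha else "non-synergistic"
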