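"""Two-stage consensus filter: examples, brute-force oracles, invariants."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinscreen import (
    ConsensusParams,
    DockingScoreTable,
    consensus_rank_of,
    load_score_table,
    per_model_percentiles,
    save_score_table,
    stage_one_consensus,
    stage_two_consensus,
    summarize_screen,
)
from kinscreen.consensus import HitEntry, TargetHitList

from conftest import random_table


# ---------------------------------------------------------------- oracles
def oracle_percentiles(scores):
    """Min-rank percentile by explicit counting, independent of rankdata."""
    n, m = scores.shape
    out = np.full((n, m), np.nan)
    for j in range(m):
        col = scores[:, j]
        valid = ~np.isnan(col)
        count = valid.sum()
        for i in range(n):
            if valid[i]:
                out[i, j] = (np.sum(col[valid] < col[i]) + 1) / count
    return out


def oracle_stage1_members(table, q, m_min):
    pct = oracle_percentiles(table.scores)
    members = {}
    for i, cid in enumerate(table.compound_ids):
        qual = [j for j in range(table.n_models) if not np.isnan(pct[i, j]) and pct[i, j] <= q]
        if len(qual) >= m_min:
            members[cid] = min(table.scores[i, j] for j in qual)
    return members


def oracle_stage2_members(hitlists, q_t, t_min):
    support = {}
    for hl in hitlists:
        for e in hl.entries:
            if e.percentile_rank <= q_t:
                support.setdefault(e.compound_id, set()).add(hl.target_id)
    return {cid for cid, ts in support.items() if len(ts) >= t_min}


# ------------------------------------------------------------------- I/O
def test_load_score_table_roundtrip():
    text = "compound_id,m1,m2\na,-9.0,-5.0\nb,-5.0,NA\nc,-1.0,-7.0\n"
    table = load_score_table(io.StringIO(text), "T1")
    assert table.n_compounds == 3 and table.n_models == 2
    assert math.isnan(table.scores[1, 1])
    buf = io.StringIO()
    save_score_table(table, buf)
    buf.seek(0)
    again = load_score_table(buf, "T1")
    assert again.compound_ids == table.compound_ids
    assert again.model_ids == table.model_ids
    np.testing.assert_array_equal(again.scores, table.scores)


def test_load_rejects_duplicate_and_non_numeric():
    with pytest.raises(ValueError, match="duplicate compound"):
        load_score_table(io.StringIO("compound_id,m1\na,1\na,2\n"), "T1")
    with pytest.raises(ValueError, match="non-numeric"):
        load_score_table(io.StringIO("compound_id,m1\na,1\nb,oops\n"), "T1")


def test_tab_delimited_autodetect():
    table = load_score_table(io.StringIO("compound_id\tm1\na\t-1.5\nb\t2.0\n"), "T1")
    assert table.scores[0, 0] == -1.5


# ------------------------------------------------------------ percentiles
def test_percentile_examples():
    t = DockingScoreTable("T", ("a", "b", "c"), ("m",), np.array([[-9.0], [-5.0], [-1.0]]))
    np.testing.assert_allclose(
        per_model_percentiles(t).to_numpy().ravel(), [1 / 3, 2 / 3, 1.0]
    )
    # fully tied column: min-rank rule puts everything at 1/n
    tied = DockingScoreTable("T", tuple("abcd"), ("m",), np.full((4, 1), 2.0))
    np.testing.assert_allclose(per_model_percentiles(tied).to_numpy().ravel(), 0.25)


def test_percentiles_match_counting_oracle(rng):
    for _ in range(20):
        t = random_table(rng, 20, 3, na_frac=0.15)
        got = per_model_percentiles(t).to_numpy()
        np.testing.assert_allclose(got, oracle_percentiles(t.scores), equal_nan=True)


def test_all_absent_column_errors():
    t = DockingScoreTable("T", ("a", "b"), ("m1", "m2"),
                          np.array([[1.0, np.nan], [2.0, np.nan]]))
    with pytest.raises(ValueError, match="m2"):
        per_model_percentiles(t)


# ---------------------------------------------------------------- stage 1
def test_stage1_inclusion_rule(rng):
    # compound in the top 10% of 6 of 10 models is kept at m_min=5
    n, m = 50, 10
    scores = rng.normal(size=(n, m))
    scores[0, :6] = -100.0  # best everywhere in six models
    scores[0, 6:] = 100.0
    t = DockingScoreTable("T", tuple(f"c{i}" for i in range(n)),
                          tuple(f"m{j}" for j in range(m)), scores)
    hl = stage_one_consensus(t, ConsensusParams(q_model=0.10, m_min=5))
    assert "c0" in hl.compound_ids()
    entry = next(e for e in hl.entries if e.compound_id == "c0")
    assert entry.n_qualifying_models == 6
    assert entry.representative_score == -100.0  # best qualifying pose


def test_stage1_matches_bruteforce(rng):
    params = ConsensusParams(q_model=0.3, m_min=4)
    for _ in range(20):
        t = random_table(rng, 20, 10, na_frac=0.1)
        hl = stage_one_consensus(t, params)
        expected = oracle_stage1_members(t, 0.3, 4)
        assert set(hl.compound_ids()) == set(expected)
        for e in hl.entries:
            assert e.representative_score == pytest.approx(expected[e.compound_id])
        # ascending by representative score, ties by id
        keys = [(e.representative_score, e.compound_id) for e in hl.entries]
        assert keys == sorted(keys)


def test_stage1_m_min_exceeds_models():
    t = random_table(np.random.default_rng(0), 5, 3)
    with pytest.raises(ValueError, match="m_min"):
        stage_one_consensus(t, ConsensusParams(m_min=4))


def test_stage1_empty_result_is_not_error(rng):
    t = random_table(rng, 3, 2)
    hl = stage_one_consensus(t, ConsensusParams(q_model=0.01, m_min=2))
    assert len(hl) == 0


# ---------------------------------------------------------------- stage 2
def _hitlist(target, ids_scores):
    k = len(ids_scores)
    entries = tuple(
        HitEntry(cid, s, 5, (r + 1) / k)
        for r, (cid, s) in enumerate(sorted(ids_scores, key=lambda x: (x[1], x[0])))
    )
    return TargetHitList(target_id=target, entries=entries)


def test_stage2_matches_bruteforce(rng):
    params = ConsensusParams(q_target=0.5, t_min=2)
    for _ in range(20):
        hitlists = [
            _hitlist(f"T{t}",
                     [(f"c{i}", float(rng.normal())) for i in rng.choice(12, 8, replace=False)])
            for t in range(4)
        ]
        final = stage_two_consensus(hitlists, params)
        assert set(final.compound_ids()) == oracle_stage2_members(hitlists, 0.5, 2)
        # ranks dense 1..K and ordered by mean supporting percentile
        assert [e.consensus_rank for e in final.entries] == list(range(1, len(final) + 1))


def test_stage2_degenerate_single_target_reduction(rng):
    t = random_table(rng, 15, 4)
    hl = stage_one_consensus(t, ConsensusParams(q_model=0.5, m_min=2))
    final = stage_two_consensus([hl], ConsensusParams(q_target=1.0, t_min=1))
    assert set(final.compound_ids()) == set(hl.compound_ids())


def test_stage2_duplicate_targets_error():
    hl = _hitlist("T1", [("a", 1.0)])
    with pytest.raises(ValueError, match="duplicate target"):
        stage_two_consensus([hl, hl], ConsensusParams(t_min=1))


def test_consensus_rank_lookup(rng):
    hitlists = [
        _hitlist(f"T{t}", [(f"c{i}", float(rng.normal())) for i in range(10)])
        for t in range(4)
    ]
    final = stage_two_consensus(hitlists, ConsensusParams(q_target=0.5, t_min=3))
    for e in final.entries:
        assert consensus_rank_of(final, e.compound_id) == e.consensus_rank
    assert consensus_rank_of(final, "nonexistent") is None
    if len(final):
        assert consensus_rank_of(final, final.entries[0].compound_id) == 1


# ------------------------------------------------------------- properties
def test_monotonicity_in_thresholds(rng):
    for _ in range(10):
        t = random_table(rng, 25, 8)
        loose = stage_one_consensus(t, ConsensusParams(q_model=0.4, m_min=3))
        tight = stage_one_consensus(t, ConsensusParams(q_model=0.2, m_min=4))
        assert set(tight.compound_ids()) <= set(loose.compound_ids())
        assert set(loose.compound_ids()) <= set(t.compound_ids)


def test_permutation_invariance(rng):
    t = random_table(rng, 20, 6)
    perm = rng.permutation(20)
    shuffled = DockingScoreTable(
        t.target_id,
        tuple(t.compound_ids[i] for i in perm),
        t.model_ids,
        t.scores[perm],
    )
    params = ConsensusParams(q_model=0.3, m_min=3)
    a, b = stage_one_consensus(t, params), stage_one_consensus(shuffled, params)
    assert a.entries == b.entries  # identical ordering and values


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(1, 30),
    m=st.integers(1, 10),
    q=st.floats(0.05, 1.0),
)
def test_stage1_oracle_property(seed, n, m, q):
    rng = np.random.default_rng(seed)
    t = random_table(rng, n, m)
    m_min = int(rng.integers(1, m + 1))
    hl = stage_one_consensus(t, ConsensusParams(q_model=q, m_min=m_min))
    assert set(hl.compound_ids()) == set(oracle_stage1_members(t, q, m_min))


def test_determinism_byte_identical(rng):
    t = random_table(rng, 30, 6)
    params = ConsensusParams(q_model=0.3, m_min=2)
    a = stage_one_consensus(t, params)
    b = stage_one_consensus(t, params)
    assert a == b


# ---------------------------------------------------------------- summary
def test_summarize_screen_fraction_and_runs(rng):
    t = random_table(rng, 10, 2)
    hl = stage_one_consensus(t, ConsensusParams(q_model=1.0, m_min=1))
    final = stage_two_consensus([hl], ConsensusParams(q_target=1.0, t_min=1))
    s = summarize_screen(100, 2, [hl], final)
    assert s.final_fraction_percent == pytest.approx(100 * len(final) / 100)
    assert s.total_docking_runs == 100 * 1 * 2
    with pytest.raises(ValueError):
        summarize_screen(0, 2, [hl], final)
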