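"""Retrospective screening power of a synthetic ensemble.

Pools each compound's ensemble-mean docking score on one target of the
synthetic screen and asks how well it separates the planted actives from
the rest: ROC-AUC (percent) and the enrichment factor in the top 1%.
"""

from kinscreen import LabelledScores, ScoredCompound, SimConfig, enrichment_factor, roc_auc, simulate_scores

tables, actives = simulate_scores(SimConfig(seed=17))
table, act = tables["T1"], actives["T1"]
mean_scores = table.scores.mean(axis=1)
data = LabelledScores(entries=tuple(
    ScoredCompound(cid, float(s), cid in act)
    for cid, s in zip(table.compound_ids, mean_scores)
))

auc = roc_auc(data)
ef1 = enrichment_factor(data, 0.01)
print(f"{data.n_actives} actives among {len(data)} compounds")
print(f"ROC-AUC: {auc:.1f}%  (50% = random, 100% = perfect ranking)")
print(f"EF(1%):  {ef1:.1f}x  (actives are {ef1:.1f}-fold concentrated in the top 1%)")
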