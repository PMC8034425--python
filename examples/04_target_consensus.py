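"""Multi-predictor target consensus: Venn membership and ranked agreement.

Three target predictors score on incomparable scales (Pa/Pi pairs,
probabilities, pharmacophore fit), so consensus uses set membership and
mean reciprocal per-predictor rank rather than mixing raw scores.
"""

from screenkit.synthetic_data import gen_predictor_outputs, predictor_fixture_lists
from screenkit.target_consensus import consensus_rank, venn_membership

lists = predictor_fixture_lists()
membership, sizes = venn_membership(lists)
print("Venn region sizes (predictor subset -> exclusive gene count):")
for preds, n in sorted(sizes.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
    print(f"  {' & '.join(sorted(preds)):35s} {n}")

triple = sorted(t for t, p in membership.items() if len(p) == 3)
print(f"\ngenes predicted by all three algorithms: {', '.join(triple)}")

entries, _ = gen_predictor_outputs(true_targets=triple, n_decoys=20, seed=1)
consensus = consensus_rank(entries, min_predictors=3)
print("\nconsensus ranking (mean reciprocal rank across predictors):")
for t in consensus[:6]:
    print(f"  {t.target:8s} predictors={t.n_predictors}  score={t.consensus_score:.3f}")

# The 6-gene triple intersection plus a 2-gene two-predictor region mirrors
# the structure of a three-algorithm target-prediction campaign.
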