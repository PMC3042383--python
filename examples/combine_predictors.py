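"""Boolean and majority-vote combination of three imperfect predictors.

Three seeded mock predictors with independent errors (80% sensitivity
and specificity each) are combined by OR, AND and majority vote.  OR
boosts sensitivity, AND boosts specificity, and the majority vote lifts
accuracy toward the closed form p^3 + 3p^2(1-p) = 0.896.  The
upper-bound error — reads every member gets wrong — floors what any
combiner could achieve.
"""

import numpy as np

from fragbench import (
    CombinationRule,
    GenomeSimConfig,
    build_benchmark,
    combine_predictions,
    generate_genomes,
    mock_predictor,
)
from fragbench.combine import upper_bound_error
from fragbench.metrics import confusion, rates

genomes = generate_genomes(GenomeSimConfig(n_genomes=8, genome_length=100_000, seed=3))
bench = build_benchmark(genomes, read_lengths=[300], n_per_type=400, seed=4)

members = [
    mock_predictor(bench, sens=0.8, spec=0.8, seed=s, name=f"mock{s}") for s in (1, 2, 3)
]
names = tuple(m.predictor_name for m in members)

print("method                     sensitivity  specificity  accuracy")
for m in members:
    r = rates(confusion(bench, m))
    print(f"{m.predictor_name:<26} {r.sensitivity:>11.3f}  {r.specificity:>11.3f}  {r.accuracy:>8.3f}")
for op in ("OR", "AND", "CONSENSUS"):
    rule = CombinationRule(op, names)
    combined, _ = combine_predictions(members, rule, bench=bench)
    r = rates(confusion(bench, combined))
    print(f"{rule.name:<26} {r.sensitivity:>11.3f}  {r.specificity:>11.3f}  {r.accuracy:>8.3f}")

truth = {f.read_id: f.is_coding for f in bench.fragments}
calls = {m.predictor_name: {rid: m.is_coding(rid) for rid in truth} for m in members}
errors = [np.mean([c[rid] != truth[rid] for rid in truth]) for c in calls.values()]
print(f"\nupper-bound error {upper_bound_error(calls, truth):.3f} "
      f"vs best single error {min(errors):.3f}")
# the upper bound marks a read correct if ANY member got it right
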