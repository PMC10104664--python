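"""Exact CRF inference on a small random instance, cross-checked against
brute-force enumeration of all label paths.

For short sequences every one of the L^n paths can be scored directly, which
verifies both the Viterbi decoder (argmax path) and the forward-recursion
log-partition (log-sum-exp over all paths).
"""

import itertools

import numpy as np

from pephat import Potentials, log_partition, path_score, viterbi_decode
from pephat.autodiff import Tensor

rng = np.random.default_rng(42)
n, L = 5, 3
potentials = Potentials(
    emission=Tensor(rng.standard_normal((n, L))),
    transition=Tensor(rng.standard_normal((n - 1, L, L))),
    start_scores=Tensor(rng.standard_normal(L)),
    end_scores=Tensor(rng.standard_normal(L)),
)

scores = {path: float(path_score(potentials, list(path)))
          for path in itertools.product(range(L), repeat=n)}
best_path = max(scores, key=scores.get)
decoded, tables = viterbi_decode(potentials)

print(f"paths enumerated: {len(scores)} (3^{n})")
print(f"enumeration argmax: {best_path}  score {scores[best_path]:.6f}")
print(f"viterbi decode:     {tuple(int(y) for y in decoded)}  "
      f"score {float(path_score(potentials, decoded)):.6f}")
logZ = float(log_partition(potentials))
print(f"log-partition: forward {logZ:.9f}  "
      f"brute force {np.logaddexp.reduce(list(scores.values())):.9f}")
print(f"sum of path probabilities: "
      f"{sum(np.exp(s - logZ) for s in scores.values()):.9f}")

# The decoded path matches the enumerated optimum, and exp(score - logZ)
# sums to 1 over all paths: the CRF is a proper distribution over labelings.
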