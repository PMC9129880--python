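"""Factorial sweep of leader interaction parameters.

Covaries the leader's contact-inhibition intensity, the group co-attraction
level and the leader cell size over their low/medium/high settings on a 1:3
chain (differential CIL), runs seeded replicates of each combination, and
counts how many parameter sets fulfil each chain-behaviour score.
"""

from crestchain.model import Arena, Composition
from crestchain.sweep import (
    DEFAULT_LEVELS,
    SCORE_NAMES,
    count_passing,
    enumerate_grid,
    run_sweep,
)

grid = enumerate_grid(
    DEFAULT_LEVELS,
    ["cil_intensity", "coattraction", "cell_size"],
    Composition.preset("1:3"),
)
print(f"sweeping {len(grid)} parameter combinations x 5 replicates ...")
result = run_sweep(grid, Arena(), n_reps=5, master_seed=1)

print("\ncombinations fulfilling each score (of", len(grid), "):")
for score in SCORE_NAMES:
    print(f"  {score:24s} {count_passing(result, score):3d}")
print(f"  {'all five':24s} {count_passing(result, 'all'):3d}")

matching = [c for c in result.combinations if c["combination_matches"]]
if matching:
    levels = matching[0]["levels"]
    print(f"\nexample matching combination: {levels}")
print("\nWith heterogeneous identities and differential CIL, many parameter")
print("sets reproduce the in-vivo chain behaviour; homogeneous chains (try")
print("composition 'all-follower' or 'all-leader') match none.")
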