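"""Reversal scenarios, polarity, branch assignment and fixation rates.

Sorts the inversion-rich A chromosome's signed permutation by reversals,
places inversions on the species tree under a single-origin assumption, and
compares lineage fixation rates with the exact conditional Poisson test.
"""

from syntevo.history import (
    assign_to_branches,
    fixation_rate,
    rate_ratio_test,
    reversal_distance,
    round_sig,
    sort_by_reversals,
)
from syntevo.synteny import SignedPermutation
from syntevo.tree import subgroup_tree

# the observed block order of a multi-inversion region (sign = orientation)
perm = SignedPermutation("A", (1, -4, 5, -2, -3, -6, 7, -8, 9, -10))
scenario = sort_by_reversals(perm)
print(f"A-chromosome permutation {perm.elements}")
print(f"minimum reversals: {reversal_distance(perm)}")
for step, (i, j) in enumerate(scenario.reversals, start=1):
    print(f"  h{step}: reverse blocks {i + 1}..{j + 1}")
print()

tree = subgroup_tree()
states = {
    "O_ms": {"madeirensis": "fixed", "subobscura": "extinct_ancestral", "guanche": "absent"},
    "E_g1": {"guanche": "fixed", "subobscura": "absent", "madeirensis": "absent"},
}
for a in assign_to_branches(states, tree):
    print(f"{a.inversion_id}: originated on branch '{a.branch}' ({a.tip_states})")
print()

cmp = rate_ratio_test(6, 1.72, 3, 4 * 1.72)
print(f"sex-chromosome rate {round_sig(fixation_rate(6, 1.72))} vs "
      f"autosomal {round_sig(fixation_rate(3, 4 * 1.72))} inversions/Myr "
      f"(ratio {round_sig(cmp.ratio)}, two-sided P = {cmp.p_two_sided:.3f})")
print()
print("The scenario shows one optimal path interconverting the two species'")
print("block orders; the branch table places each inversion on the earliest")
print("branch consistent with all carriers (extinct-ancestral = replaced by")
print("nested derivatives); and the rate test shows the ~8x faster fixation")
print("on the sex chromosome.")
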