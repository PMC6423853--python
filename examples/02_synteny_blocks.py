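"""Signed synteny blocks and per-chromosome signed permutations.

Compares the simulated mainland genome against the island lineage: shared
markers become anchors, collinear anchor runs become blocks, and block order
with orientation yields the signed permutation each chromosome hands to the
reversal-history stage.
"""

from syntevo import simulate
from syntevo.synteny import block_stats, chain_blocks, find_anchors, to_signed_permutation
from syntevo.tree import subgroup_tree

tree = subgroup_tree()
ancestral = simulate.template_genome(scale=0.02, markers_per_mb=400, seed=7)
events = simulate.plan_events(ancestral, tree, simulate.paper_template_specs())
sim = simulate.evolve_subgroup(ancestral, tree, events, outgroup="outgroup", seed=7)

anchors = find_anchors(sim.genomes["subobscura"], sim.genomes["guanche"])
blocks = chain_blocks(anchors, min_anchors=3, max_gap=50_000)
stats = block_stats(blocks)
print(f"{len(anchors)} anchors -> {stats.n_blocks} blocks "
      f"(mean {stats.mean_size_mb:.3f} Mb on the reference, {stats.n_inverted} inverted)")
print()
for chrom in ("A", "J", "U", "E", "O", "dot"):
    perm = to_signed_permutation([b for b in blocks if b.chrom1 == chrom], chrom)
    print(f"chr {chrom:3s} signed permutation: {perm.elements}")
print()
print("Negative elements are blocks lying in inverted orientation relative to")
print("the island genome; an identity permutation (like the dot) means the")
print("chromosome is collinear. The inversion-rich A chromosome fragments")
print("into the most blocks, mirroring its faster structural evolution.")
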