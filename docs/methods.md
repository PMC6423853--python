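# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the simulation-based tests do and do not establish.

## Coordinates and containers

All internal coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted only in the readers/writers. Chromosomes are
acrocentric by convention: position 0 is the centromere end, `length` the
telomere end, so "proximal" always means centromere-ward. A `MarkerGenome`
is an ordered set of chromosomes, each carrying sorted, non-overlapping
oriented gene markers over an optional nucleotide sequence; marker ids are
the ortholog keys that downstream anchoring relies on (one-to-one
orthology only — paralogy is rejected).

## Simulator

The generator emulates the study system's setting: six chromosomes (five
rods of ~21–30 Mb and a ~1.4 Mb dot, scalable), markers placed uniformly
without overlap with random strands, and intergenic sequence drawn i.i.d.
at GC 45%. One top-level seed is split hierarchically (numpy
`SeedSequence.spawn`) per chromosome and per sampling step, so identical
configurations reproduce byte-identical FASTA/GFF3/BED output.

### Inversion mechanisms

* **straight** — `s[l:r]` is reverse-complemented in place; markers inside
  are reversed in order with strands flipped; length unchanged.
* **staggered** — offset cuts duplicate the two stagger fragments in
  inverted orientation on the flanks of the derived arrangement:

  `derived = s[:l] + s[l:l+oL] + revcomp(s[l:r]) + s[r-oR:r] + s[r:]`

  The genome grows by `oL + oR`. Where only the resulting footprint is
  observable, the exact cut geometry is a convention; this one places each
  fragment forward on its own flank and its inverted duplicate at the
  facing end of the inverted segment, so each flank carries an inverted
  copy of the opposite flank's fragment. Whether the duplicates sit inside
  or outside the inverted segment is not observable from a single derived
  genome, so the choice is documented rather than asserted. The template
  history uses single-sided offsets (`oR = 0`), so each staggered event
  carries one duplication whose length is the event's reported footprint —
  matching how such duplications are reported (one length per inversion).
  Stagger fragments must be marker-free; default simulated lengths bracket
  0.3–1.2 kb, spanning the observed 513–1007 bp footprints.
* **ectopic** — requires a pre-placed pair of inverted repeat copies
  (`place_inverted_repeat_pair`); the segment between the copy midpoints
  is inverted, which reconstitutes a full-length copy on each flank, so
  repeats flank the breakpoints of both the ancestral and derived
  arrangements — the diagnostic footprint of this mechanism.

Breakpoints must be intergenic unless `disrupt=True`, in which case the
straddled marker is split into `.5p`/`.3p` pieces (this is what makes a
simulated gene disruption visible to the disruption test downstream).

### Histories

Events are addressed to named tree branches and applied in listed order
along each root-to-tip path. The default tree is
`((mainland:0.92, island_sister:0.92)ms:0.80, island:1.72)` in Myr — 1.72
to the subgroup ancestor, 0.92 to the sister split. Polymorphic events are
restricted to terminal branches (an internal-branch polymorphism would
segregate across species, outside this system's setting); a tip carrying
any emits a second, standard haplotype without them. The truth table
records each event's realized breakpoints per tip after all coordinate
shifts from earlier events on the same chromosome (shifts are
chromosome-scoped). For a staggered event the realized span is the outer
hull `[l, r + oL + oR]` — the junctions where collinearity with an
unrearranged genome breaks.

Scenario specs (`EventSpec`) give breakpoints as chromosome-length
fractions; `plan_events` replays the tree and snaps each cut to the
midpoint of the nearest intergenic gap wide enough for its stagger
fragment, so planned scenarios are valid by construction.

### Repeat landscapes

`place_repeats` samples per-class, per-chromosome repeat midpoints from a
discretised density `w(x) = (1 + (E−1)·e^(−10x/L)) · max(0, 1 + s·(x −
L/2)/10⁶)`: a pericentromeric enrichment factor E decaying over the first
~10% of the chromosome, and a linear telomere-ward gradient of s per Mb
centred mid-chromosome. With E = 1 and s = 0 this reduces exactly to the
uniform law (the calibration tests rely on this). The defaults echo the
study system: transposons and satellites enriched toward the centromere,
microsatellites rising toward the telomeres.

## Synteny

Anchors are markers shared by id; the relative strand is the product of
the two genomes' marker strands. Chaining is greedy over genome1-sorted
anchors within each chromosome pair: a run keeps one relative strand, must
be consecutive in the rank order of **both** genomes (this makes chaining
symmetric under swapping the genomes), and keeps inter-anchor gaps within
`max_gap` on both sides. Runs shorter than `min_anchors` are treated as
micro-rearrangements: their anchors are dropped and chaining repeats until
stable, so a stray anchor does not break an otherwise collinear block.
Defaults are `min_anchors=3` and `max_gap=1 Mb` at full scale (tests scale
`max_gap` to ~1/20 of the chromosome); both are exposed in the config
since the reference mapping tool's internal defaults are not reproduced
here. Block numbering follows genome2 order (ties by genome2 start), so
the signed permutation is the identity exactly when the chromosome pair is
collinear.

## Breakpoints

A breakpoint is the interval between two contiguous blocks on the
reference genome (zero-length when blocks abut). Flank queries take the
interval plus `flank_width` (default 5 kb) into each bounding block.

Flank-to-genome mapping uses exact seed-and-extend (sparse `str.find`
seeds, diagonal clustering, base-wise extension): the simulator introduces
no substitutions, so cross-genome homologs are exact copies and a
quadratic local alignment of multi-kb queries against whole chromosomes
would buy nothing. The affine-gap local aligner (match +1, mismatch −2,
gap open −4, extend −1; Biopython's `PairwiseAligner`) is used where
length/identity thresholds matter: inverted-duplication detection aligns
one flank window against the reverse complement of the other, after a
12-bp exact-seed prescreen that bounds the aligned slice (a reportable
duplication must therefore retain one 12 bp exact stretch — comfortably
implied by the 0.9 identity floor in practice). Alignment ends are trimmed
to solid exact-match runs (≥10 matching columns) before measuring length:
local alignments otherwise over-extend a few bases across coincidental
matches, and a duplication's true termini are long exact runs. Reported
lengths land within ±5 bp of simulated footprints of 513–1007 bp.

Reciprocal consistency compares junction estimates, not window bounds:
direction 1→2 implies a breakpoint coordinate in genome 2 (the hit
terminus facing the query's breakpoint interval); direction 2→1 refines
the breakpoint on its own genome the same way; the directions agree when
these coincide within `tol` (default 1 kb). Mechanism classification then
follows the footprint table: duplication in the derived arrangement only →
staggered; in both → ectopic recombination; in neither → straight or
nearly straight (stagger fragments below the 50 bp detection floor leave
no lasting trace); ancestral-only → undetermined (flagged, never guessed).

Gene disruption is half-open interval intersection between a breakpoint
interval and the gene bodies; zero-length intervals are tested as a point
strictly inside a body, so a cut exactly at a gene boundary does not count.

## History

**Polarity.** Marker-order windows (3 markers a side by default) around a
breakpoint are compared against the outgroup's order of the same ids; a
whole-window reversal is treated as a match, since it is the same local
arrangement read from the other strand. The derived junction juxtaposes
different genes, so either an order or a content difference marks the
derived arrangement. Windows sharing too few markers with the outgroup
yield `undetermined` — the call never guesses.

**Reversal distance.** Exact Hannenhalli–Pevzner: the signed permutation
is expanded to 2n+2 framed points; cycles are traversed over alternating
black (position) and gray (value) pairings; components are connected sets
of cycles under gray-edge interleaving, oriented iff some gray edge has
same-parity endpoints; hurdles are the unoriented components that do not
separate two other unoriented components on the frame-closed circle
(computed directly from arc membership); a fortress is scored when an odd
number of hurdles are all superhurdles (removal of any would promote a
protected component). `sort_by_reversals` greedily takes, at each step,
the lexicographically smallest `(start, end)` reversal that lowers the
exact distance, giving the lexicographically smallest optimal scenario;
cost is O(d·n²) distance evaluations, trivial at block counts ≤ ~15.
Tests verify distances against a full-group BFS for all signed
permutations with n ≤ 5 and an IDA* search (admissible cycle bound) for
200 random permutations with n ≤ 8. The distance symmetry that holds —
and is property-tested — is the conjugate flip (reverse element order,
complement magnitudes k → n+1−k, keep signs: viewing both chromosomes
from the opposite telomere); a plain reverse-and-negate changes the
distance in general.

**Branch assignment.** Single-origin (Dollo-like): each inversion is
placed on the branch above the most recent common ancestor of all taxa
whose history contains its derived state (`fixed`, `polymorphic`, or
`extinct_ancestral` — present ancestrally but replaced by nested
derivatives). Any tip below that branch reported `absent` is a conflict
and raises with the taxa named.

**Rates.** `fixation_rate` is k/t in inversions/Myr, displayed at 2
significant figures. The exact rate comparison conditions on the total
count: k₁ ~ Binomial(n, t₁/(t₁+t₂)) under equal Poisson rates; the
one-sided tail follows the observed direction and the two-sided p doubles
the smaller tail (capped at 1) — a documented choice, since a bare
"Poisson distribution" label is ambiguous. The per-average-autosome
exposure convention (divide autosomal time by the four large autosomes,
dot excluded) is adopted because it reproduces the 0.44 vs 3.5
inversions/Myr contrast and its 8-fold ratio.

## Genome statistics

The G-test uses natural logs, `G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ)` with `Eᵢ`
proportional to chromosome length; zero cells contribute 0; p is the
chi-square upper tail on k−1 df. This formulation reproduces the printed
gene-count statistic (113.61 on the published counts and lengths) and is
calibrated (type-I error ≈ 5% at α = 0.05 under the multinomial null).
Window profiles count repeat midpoints in windows tiled centromere to
telomere (default 500 kb window, 250 kb step at full scale, scaled in
tests); the random-placement envelope is the per-window 2.5/97.5
percentile over B = 1000 seeded uniform placements — Monte-Carlo rather
than analytic, to avoid assuming independence across overlapping windows.
Regressions and correlations are ordinary least squares / Pearson via
scipy. N50 is the scaffold length at which half the assembly is in
scaffolds that size or larger; L50 is that scaffold's rank. Display
conventions (rates 2 s.f., density 2 d.p., fold to nearest integer) are
applied by helpers; raw values are always retained.

## Problem sizes

Tests and the acceptance script run the pipeline at 1/50 of the real
karyotype (~2.5 Mb per genome) with ~400 markers/Mb and 300 bp markers —
dense enough that every template block holds ≥3 anchors and stagger
fragments up to ~1.1 kb fit intergenic gaps. Mechanism-recovery trials use
60 kb single-chromosome sequences (100 trials per mechanism);
breakpoint-localization worlds use 200 kb chromosomes with 40 markers;
calibration suites use 1000 null tables / 100 envelope runs.

## What the simulations do and do not show

The generator produces exact sequence copies across genomes: no
substitutions, indels, or assembly error. Recovery results (duplication
lengths to ±5 bp, 100% mechanism accuracy, full polarity/branch recovery)
therefore demonstrate the correctness of the logic, not robustness to
divergence — on real genomes, alignment identity < 1 and breakpoint-region
repeats would add noise the thresholds (`min_dup_len` 50 bp,
`min_identity` 0.9, `tol` 1 kb) are designed to absorb but that these
tests do not exercise. Block counts and sizes at test scale are not
comparable to full-genome values. In multi-inversion regions with shared
or clustered breakpoints, per-block mechanism calls are fragmentary; the
reversal scenario, not the per-block table, is the unit of inference there
— mirroring how overlapping-inversion regions are analysed in practice.

## Known limitations

Only paracentric inversions are modelled: no translocations,
transpositions, duplicative transposition, or nucleotide-level evolution;
one chromosome pair per signed permutation (translocated blocks raise).
Paralogy is unsupported (duplicate marker ids are an error). Polymorphic
arrangements are realized as two haplotype genomes per tip, not population
frequencies. The mechanism classifier reports `undetermined` for
ancestral-only duplications rather than inventing a fourth mechanism.
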