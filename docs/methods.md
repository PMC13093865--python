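# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic benchmarks do and do not demonstrate.

## Distances

All pairwise comparisons are uncorrected p-distances under **pairwise
deletion**: only columns where both sequences carry an unambiguous A/C/G/T
are compared. IUPAC ambiguity codes, Ns and gaps are missing data, never
partial matches. With barcodes ranging from 300 to 658 bp, complete
deletion would discard most of the alignment, so pairwise deletion is the
only workable convention; its cost is that different pairs are measured on
different site sets, which we bound by declaring a distance undefined below
`min_overlap` (default **100** jointly unambiguous sites — small enough
that any 300 bp+ pair overlapping the same half of the barcode is usable,
large enough that a distance is never estimated from a handful of sites).

Length tiers (≥ 300, ≥ 600 bp) are measured on the count of unambiguous
A/C/G/T characters, not the aligned column span, matching the intent of
"bp" for partial barcodes padded with Ns. The barcode-gap verdict uses a
strict inequality (max intra < min inter); ties count as no gap. Barcode
sharing requires the minimum interspecific distance to be exactly zero,
which with pairwise deletion means two sequences identical at every jointly
unambiguous site over at least `min_overlap` columns. The median
intraspecific distance is the median over all intraspecific pairs (not over
per-sequence statistics); the median minimum interspecific distance is the
median over the focal species' sequences of each sequence's own minimum to
a congeneric heterospecific. Distances are computed on the extended-study-
area subset of records (`in_extended_area`).

Records determined only as a species group/complex or to genus level are
excluded from every per-species statistic and map; maps additionally admit
"cf." determinations.

## Stop-codon screening

Sequences are screened for internal stop codons — the classic NUMT
signal — by translating the gap-stripped sequence in all three forward
frames under the invertebrate mitochondrial code (translation table 5,
stops TAA/TAG). Codons containing ambiguity codes are skipped. Because the
amplicon frame of a partial barcode is not known in advance, the frame with
the fewest stops wins (ties to the lower frame index), and the sequence
fails only if that best frame still contains a stop. Sequences with fewer
than three unambiguous codons in every frame are reported *indeterminate*
rather than failed.

## Coordinates

Coordinates are WGS84 decimal degrees. Toponym-derived coordinates are
snapped to a 0.1° grid by rounding half away from zero (the same rounding
used for all printed percentages); records known only to country level
carry no coordinates and are never plotted.

## Monophyly classification

Classification is purely topological on a rooted tree (branch lengths and
support labels are ignored; polytomies allowed). A species is monophyletic
when the MRCA clade of its tips contains no other species — including a
multifurcating MRCA, and including a single tip in a monotypic genus group.
A single tip in a non-monotypic group is a singleton. The
paraphyly/polyphyly boundary is **convexity**: a non-exclusive species is
paraphyletic exactly when its Steiner tree (the minimal subtree connecting
its tips, equal to the union of tip-to-MRCA paths) shares no node with any
other species' Steiner tree, polyphyletic otherwise. This operational rule
is the normative definition here — published monophyly checkers do not
document their tie handling — and it is validated against a
first-principles brute force (explicit leaf-set and path enumeration) over
all rooted binary topologies with up to 7 tips and up to 3 species, and a
seeded sample of 8-tip topologies; exhausting 8 tips outright would cost
~10⁸ classifier calls for no additional structural coverage, as every
para/poly configuration class already occurs by 7 tips.

One consequence of the convexity rule: a species interrupted only by
singleton intruders stays paraphyletic, because a single tip's Steiner tree
is just that tip and tips cannot lie on another species' path.

Lineage counting is independent of classification: the number of maximal
clades whose tips all belong to the focal species. These clades partition
the species' tips, one lineage per species means monophyly, and the count
never exceeds the tip count.

Rooting uses the edge subtending the smallest clade containing all
designated outgroups; if the outgroups are not separable the tree is rooted
on the first outgroup's pendant edge and a warning is logged. A single
outgroup is tolerated with a warning (two or more are recommended).
Outgroup tips are removed before classification and never count as
intruders. Pruning to identified tips suppresses degree-2 nodes and sums
branch lengths through them, conserving root-to-tip path lengths.

## Haplotype networks

Haplotype identity is equality at all jointly unambiguous sites. Ambiguity
codes make this relation non-transitive, so collapsing is greedy in a fixed,
documented order — descending effective length, ties by specimen id — each
sequence joining the first existing haplotype whose representative (the
longest member) it matches. Network eligibility follows the map rules:
identified or cf. sequences with ≥ 600 bp, at least three sequences and at
least three haplotypes.

The network is the union of minimum spanning trees of the complete
haplotype graph weighted by Hamming distance (mutation counts over jointly
unambiguous sites). Each round runs Kruskal's algorithm with ties broken by
a fresh random permutation from the seeded generator; the union accumulates
until **50** consecutive rounds add no edge, capped at **2000** rounds.
The replicate count of the original randomized-MST formulation is not
published; these defaults make the probability of missing a tied edge in
realistic networks negligible while keeping runs instant, and on small
fixtures the union provably equals the set of edges occurring in at least
one MST (checked by exhaustive spanning-tree enumeration in the tests).

## PCoA colours and maps

Colour assignment uses classical PCoA: double-centre the squared distance
matrix, eigendecompose, keep the top two positive axes scaled by the square
root of their eigenvalues. Axis signs are made deterministic by requiring
the lexicographically first haplotype with a non-negligible coordinate to
be non-negative on each axis, so colours are invariant to input order. The
configuration is min-max scaled per axis onto the unit square (a degenerate
axis collapses to 0.5) and coloured by bilinear interpolation between blue
(0,0,255) at (0,0), yellow (255,255,0) at (1,0), green (0,255,0) at (0,1)
and red (255,0,0) at (1,1), rounding half away from zero; the corner
orientation is configurable. Note the centre of the square is
(128,128,64), the componentwise mean of the four corners, not a neutral
grey. Species with fewer than three sequences or zero maximum intraspecific
distance are drawn entirely grey (128,128,128).

Grid aggregation pads the bounding box of plotted coordinates by 2% per
side and divides the longer side by `cell_target` (default **18**, an
operationalization of "cell size proportional to the plotted area");
island-labelled records always form island-exclusive cells, driven by
metadata rather than coastline geometry so no shapefiles are needed. Every
plotted layer (cell sectors, specimen markers — diamonds for faunistic
novelties) is emitted as a TSV twin; images are convenience output only.

## Synthetic data

The generator emulates a barcode genus, not ant biology: a pure-birth
species tree whose split heights are remapped so the shallowest
between-species divergence equals `target_inter_min` (default **0.08**)
and the deepest stays below ~0.22, the realistic ceiling for congeneric
COI; the remapping passes through the inverse Jukes–Cantor transform so
*expected observed* p-distances land on the targets. Specimens hang off
species tips as stars with branches uniform on `[0, target_intra_max/2]`
(default target **0.02**). Sequences (default **658** bp) evolve site-wise
under Jukes–Cantor; mutations that would create a frame-1 stop codon are
resampled, so all emitted data pass screening. Introgression is modelled as
verbatim haplotype transfer (donor copies replacing recipient sequences),
degradation as tail-masking with N down to a target effective length in
[300, 599]. Coordinates come from per-species Gaussian clusters
(σ = 0.5°) inside a European-like window, with specimens associated to
clusters with probability **0.8** to create mappable spatial structure.

The truth table's realized statistics are computed by a plain all-pairs
loop over the emitted sequences, deliberately independent of the vectorised
distances module, so it can act as an oracle.

What passing on synthetic data shows — and does not. The simulator has a
single substitution rate, no rate heterogeneity, no indels, no within-
species tree structure beyond a star, and no misidentification; it
therefore validates the *computations* (distances, verdict logic, tree
classification, network construction, colouring) exactly, but says nothing
about how the diagnostics behave under NUMT contamination, alignment error
or taxonomic error in real libraries. Richer simulators can be slotted in
behind the same truth-table interface.

## Problem sizes

The test-suite defaults are sized for interactive runs: simulated genera of
6 species × 3–10 specimens, 20 replicate simulations for gap/sharing
recovery, exhaustive topology enumeration to 7 tips with a 400-tree sample
at 8, and MST fixtures of ≤ 6 haplotypes (where exhaustive spanning-tree
enumeration is cheap). The acceptance script uses the same scales with
seeds derived from `--seed`.
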