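# antatlas

Analytics for curated COI DNA-barcode reference libraries, built around the
workflow used for continental barcode atlases of ants: per-species genetic
distance summaries with barcode-gap and barcode-sharing diagnostics,
gene-tree monophyly classification with mitochondrial lineage counting,
haplotype networks via randomized minimum spanning trees, and PCoA-based
colour assignment for mitochondrial genetic-diversity maps. A synthetic-data
generator with known ground truth makes the whole pipeline testable without
downloading a single sequence.

## Who this is for

Curators of barcode reference libraries and phylogeographers who have, per
genus, an aligned COI FASTA and a specimen metadata table (taxonomy,
determination status, WGS84 coordinates, provenance and type-material
flags), plus optionally genus-level gene trees in Newick, and want the
standard library-quality diagnostics computed reproducibly.

## The statistics at the core

All distances are uncorrected *p*-distances with pairwise deletion: for
sequences *x*, *y* aligned over *L* columns,
*p(x,y) = |{i : xᵢ ≠ yᵢ}| / |{i : xᵢ, yᵢ ∈ {A,C,G,T}}|*, undefined below a
minimum overlap (default 100 sites). Per species the library reports:

- **max / median intraspecific distance** over identified sequences with
  ≥ 600 unambiguous bp (species with ≥ 3 such sequences), plus a looser
  maximum admitting "cf." determinations and ≥ 300 bp;
- **min interspecific distance** to any congeneric heterospecific sequence
  and the **median of per-sequence minima** (monotypic genus groups are not
  analysed; genera known to be mutually non-monophyletic, e.g.
  *Strongylognathus*/*Tetramorium*, are merged first);
- **barcode gap**: max intraspecific strictly below min interspecific;
- **barcode sharing**: min interspecific exactly zero (an identical
  haplotype in two species — introgression, incomplete lineage sorting, or
  misidentification).

On a rooted genus gene tree each species is **monophyletic** (its tips form
an exclusive clade), **paraphyletic** (non-exclusive but its minimal
connecting subtree is node-disjoint from every other species'),
**polyphyletic** (entangled), or a **singleton**; the number of
mitochondrial lineages is the number of maximal clades containing only that
species. Haplotype networks are the union of minimum spanning trees over
the haplotype Hamming graph under randomized tie-breaking, so every equally
parsimonious connection is kept. For the diversity maps, a classical PCoA
of the haplotype distance matrix is scaled onto the unit square and
bilinearly coloured between blue/yellow/green/red corners; species with
fewer than three sequences or no variation are drawn grey.

## Worked example

```python
from antatlas import (SimConfig, simulate_genus, species_summaries,
                      summarize_library, read_gene_tree, classify_all)

cfg = SimConfig(n_species=6, seqs_per_species=(3, 10), seed=42)
aln, records, truth, newick = simulate_genus(cfg)
for s in species_summaries(aln, records):
    print(f"{s.species}: n={s.n_strict} max_intra={s.max_intra:.4f} "
          f"min_inter={s.min_inter:.4f} gap={s.gap} sharing={s.sharing}")
```

prints

```
Simulatus sp01: n=7 max_intra=0.0243 min_inter=0.0957 gap=True sharing=False
Simulatus sp02: n=4 max_intra=0.0152 min_inter=0.2158 gap=True sharing=False
Simulatus sp03: n=9 max_intra=0.0167 min_inter=0.1049 gap=True sharing=False
Simulatus sp04: n=6 max_intra=0.0198 min_inter=0.1018 gap=True sharing=False
Simulatus sp05: n=7 max_intra=0.0152 min_inter=0.0745 gap=True sharing=False
Simulatus sp06: n=5 max_intra=0.0213 min_inter=0.0745 gap=True sharing=False
```

Each simulated species keeps its maximum intraspecific divergence at or
below the configured 2% and its nearest congener at or beyond 8%, so every
species shows a barcode gap and no sharing — exactly what the truth table
reports. Adding `introgression_pairs=((0, 1),)` to the config plants an
identical haplotype in two species, which the sharing verdict then flags.
Library-level reporting aggregates the same verdicts:

```python
tree = read_gene_tree(newick, records, [])
summarize_library(species_summaries(aln, records), records, classify_all(tree))
# {'n_sequences': 38, 'n_species': 6, ..., 'pct_gap': 100.0,
#  'pct_sharing': 0.0, 'pct_monophyletic': 100.0}
```

The same operations are exposed on the command line (`antatlas simulate`,
`validate`, `filter`, `distances`, `monophyly`, `network`, `maps`); every
plotted map layer is also written as a TSV twin so results never have to be
read off an image.

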