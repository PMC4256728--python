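# repeatscape

Repeat-landscape analysis of large plant genomes from **low-coverage,
unassembled short reads**. When a genome is too large or too repetitive to
assemble, its repetitive fraction can still be characterized directly from
a sub-1× shotgun sample: reads from the same repeat family find each other
by sequence similarity, and the size of the resulting read cluster measures
the family's share of the genome. This package implements that workflow as
a tested Python library — built around the kind of survey used for the two
*Coix* genomes (adlay and its wild relative), where graph-based clustering,
satellite monomer analysis, CenH3 ChIP enrichment, cross-species
comparison and RT-domain phylogenetics together describe two related
genomes that were never assembled.

## What it computes

- **Similarity-graph clustering** (`repeatscape.clustering`): reads become
  vertices; verified overlaps (≥90% identity over ≥55% of the shorter
  read, seeded by window minimizers) become edges; connected components
  are repeat families. A family's **genome proportion (GP)** is the
  percentage of analyzed reads it absorbed. Greedy layout consensus
  produces per-cluster contigs.
- **Annotation** (`repeatscape.annotation`): contigs vs a repeat library
  (identity > 70%, query coverage > 50%, strict), organelle-cluster
  elimination, the per-superfamily proportion table with retroelement /
  DNA-transposon subtotals, and masking-style per-read annotation.
- **Satellites** (`repeatscape.satellite`): tandem monomer period from
  k-mer recurrence with a lag self-identity criterion (robust to
  variant-induced phase jumps), canonical rotation/strand-invariant
  consensus, and deletion-variant quantification by spliced read
  alignment — e.g. a 102 bp variant of a 153 bp centromeric monomer,
  reported as its estimated share of monomer copies.
- **ChIP enrichment** (`repeatscape.chip`): reference-free mapping of
  ChIP reads onto clusters (≤3 edits incl. ≤2 gaps, best single cluster),
  input-normalized fold enrichment calibrated by negative-control
  clusters.
- **Comparative tables** (`repeatscape.comparative`): pooled multi-species
  clustering with per-species GP, shared/species-specific presence
  patterns, flow-cytometry genome sizing and fold ratios.
- **Phylogenetics** (`repeatscape.phylogeny`): RT-domain representative
  selection by six-frame translation, progressive peptide alignment,
  p-distances, classical neighbor joining with bootstrap supports, clade
  assignment by nearest reference leaf.
- **Synthetic data** (`repeatscape.simulate`): genomes with planted
  families at controlled GP, satellite arrays with variant monomers,
  paired-end read sets and fold-enriched ChIP/input sets — with exact
  truth tables, so every stage above is tested against ground truth.

A thin CLI (`repeatscape run CONFIG.yaml`, plus `simulate`, `stats`,
`genome-size`) drives the full pipeline from FASTQ to report tables; the
`examples/` directory shows each capability from Python.

## Worked example

Plant four repeat families at known proportions, sample paired 100 bp
reads, cluster, and compare estimated genome proportions with the truth
(`python examples/02_simulate_and_cluster.py`):

```
3000 reads, 11731 similarity edges, 4 detailed clusters

cluster  reads  est GP%  planted family (truth GP%)
CL1        268    8.93   COPIA1 (8.00)
CL2        206    6.87   GYPSY1 (5.87)
CL3        147    4.90   MUDR1 (4.00)
CL4        121    4.03   CENT1 (5.00)

total repeat fraction: 24.73% (planted 22.86%)
```

Each detailed cluster corresponds to one planted family and its GP —
cluster reads as a percentage of all reads — tracks the planted fraction
within sampling noise; the remaining reads stay as singletons or small
chains and count as single-copy DNA.

Satellite variant quantification
(`python examples/04_satellite_variants.py`):

```
detected monomer period: 153 bp (canonical consensus, first 40 bp: AAAA...)
4470 satellite reads analyzed
variant monomer: 102 bp (deleted 51 bp at monomer position 142), 27 supporting reads
  estimated 1.32% of monomer copies (planted 1.36%); raw read share 0.60%
```

The detector recovers the 153 bp period, finds the 102 bp deletion form,
and its copy-share estimate (junction-spanning reads rescaled by the
period/detection-window ratio) matches the planted fraction; the raw read
share is lower because only reads spanning the deletion junction can
reveal it.

## Layout

```
src/repeatscape/   library (io, simulate, clustering, annotation,
                   satellite, chip, comparative, phylogeny, pipeline, cli)
examples/          one short runnable script per capability
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance script
docs/methods.md    models, parameters, design choices, limitations
```
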