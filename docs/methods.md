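# Methods

`repeatscape` re-implements, as a tested library, the comparative
repeat-landscape workflow used for low-coverage surveys of large plant
genomes: repeat families are inferred directly from unassembled short
reads by similarity-graph clustering, annotated and quantified as genome
proportions, probed for satellite structure and monomer variants, scored
for CenH3 ChIP enrichment without a reference genome, compared across
species, and classified phylogenetically by their RT domains. This note
records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## Similarity-graph clustering

**Model.** Reads are vertices; an edge joins two reads whose best overlap
alignment reaches `min_identity` (default 90%) over at least
`min_overlap_fraction` (default 0.55) of the shorter read. Connected
components are repeat families; a family's genome proportion (GP) is
100 × its read count / all analyzed reads. Reads in clusters below the
`detail_threshold` fraction of reads (default 0.005%, the threshold used
for detailed analysis at tens-of-millions-of-reads scale) or in
singletons count as non-repetitive. An optional Louvain partition is
available for graphs where families share mobile domains; components are
the default because they are oracle-checkable (union–find equivalence is
asserted in the tests).

**Candidate pairing.** Exhaustive all-pairs alignment is quadratic, so
candidate pairs come from shared window minimizers: canonical 17-mers
(`kmer_length`), window 8 (`minimizer_window`). Minimizer selection
depends only on local sequence, so two overlapping reads pick the same
seeds regardless of their relative offset — strided sampling, by
contrast, only finds pairs whose offset is a multiple of the stride. Each
candidate pair's modal seed diagonal fixes a relative offset and
orientation; the implied overlap is verified with edit-distance alignment
(edlib), and identity is computed over the overlap. The tests check the
builder against a brute-force all-pairs, all-offsets oracle: seeds may
miss a sparse pair (≥90% of oracle edges required) but never invent one.

**Contigs.** Per cluster, a greedy layout seeded at the highest-degree
read places reads by breadth-first propagation of edge offsets and
orientations; the consensus is a per-column majority vote. Exactness is
tested on tiling layouts including mixed strands. Tandem arrays wrap:
because the modal diagonal between two satellite reads is the smallest
compatible offset, a satellite contig converges to roughly one monomer
plus one read length. The satellite detector is designed around this
(below).

**Operating regime.** Single-linkage chaining needs the read density on a
family *template* (all copies superimposed) to be high enough that
overlap gaps above `1 - min_overlap_fraction` of a read are rare; at
0.5× genome coverage this holds for families at ≥4% GP with templates of
a few hundred bp, which is how the synthetic recovery checks are sized.
Conversely, at several-fold coverage, chains of background reads attach
to family copy boundaries and inflate GP estimates by a few percent
relative — visible in the examples, and the reason the generator keeps a
minimum background spacer between planted blocks (see below).

## Annotation

Contigs are aligned to a user-supplied repeat library (FASTA named
`id#Superfamily`, the RepeatMasker convention). The shorter sequence of
each pair is aligned as an infix of the longer on both strands; a hit
needs identity > 70% and query coverage > 50%, both strict. Coverage is
*query* coverage (the aligned fraction of the contig or read): with short
queries against long references this is the reading under which the
screen behaves sensibly, and it makes the 50% boundary exactly testable.
A cluster's superfamily is the plurality vote of its contigs weighted by
read support; ties resolve conservatively to Unclassified; a cluster with
no passing hit but tandem structure is called Satellite. Clusters hitting
an organelle reference are eliminated before any totals. The superfamily
summary reproduces the standard table arithmetic: a retroelement subtotal
(Ty1/Copia + Ty3/Gypsy + Unclassified LTR + LINE/SINE), a DNA-transposon
subtotal, rDNA, Satellite, Unclassified, and a grand total, at two
decimals with half-up rounding.

## Satellite monomers and deletion variants

**Period detection.** Candidate periods are (a) every small period below
24 bp by direct scan and (b) the modal recurrence distances of exact
12-mers, plus ±1 and all divisors (so a higher-order repeat cannot mask
the true unit). A candidate `p` qualifies by lag self-identity: the
fraction of positions `i` with `s[i] == s[i+p]` must reach 0.80. This
criterion measures copy-to-copy identity directly and tolerates the phase
jumps that deletion-variant copies introduce: one 102 bp copy in a 153 bp
array shifts every downstream copy by −51, which destroys a global
fold-consensus criterion on long arrays but costs the lag criterion only
the ~p positions around each jump. The smallest qualifying period wins;
minimality is property-tested against a brute-force period scan. Periods
up to (length − 12) are allowed when backed by a ≥3-count recurrence
distance, because assembled satellite contigs hold little more than one
monomer plus a partial second copy. The consensus is majority-voted over
the most phase-coherent window and reported canonically — the
lexicographically minimal rotation of the lexicographically smaller
strand — making it rotation- and strand-invariant.

**Variant detection.** A read spanning an internal monomer deletion
cannot reveal it through a single cheapest edit path: for a deletion
comparable to the read length, misaligning the shorter flank as
substitutions (~0.75 edits/bp) is always cheaper than one gap position
per deleted base. Variants are therefore found by spliced alignment: the
read prefix and suffix are aligned semi-globally to a tandem repetition
of the consensus (vectorized edit-distance DP) with one free jump allowed
between them. A jump is accepted when anchored by ≥15 read bases on both
sides, its split cost is ≤8 edits, it undercuts the jump-free alignment
by ≥6 edits, and its length modulo the period is a net deletion of ≥10 bp
(a whole-monomer jump is no variant). Jumps recurring at the same monomer
position (±5 bp) and length (±2 bp) across ≥5 reads define a variant —
the support floor excludes sporadic alignment artifacts at desk-scale
depths.

**Variant fraction.** Two quantities are reported. `read_fraction` is the
raw observable: deletion-supporting reads as a percentage of family
reads. `family_fraction` estimates the percentage of monomer *copies*
carrying the variant: a read only reveals the junction when it spans it
with both anchors, a window of (read length − 2 × anchor) bases per
variant copy, so the raw read fraction understates the copy fraction by
about window/period; `family_fraction` rescales by period/window. On
simulations with 1% variant copies the rescaled estimator is unbiased
(checked over 20 seeds); the raw read share for 100 bp reads and a 153 bp
monomer is ~0.45× the copy share. The ChIP-side analogue
(`chip_satellite_variant_share`) applies the same estimator to the ChIP
reads assigned to the satellite cluster.

## ChIP enrichment without a reference

ChIP and input reads are matched against the genomic reads that
constitute each cluster: a hit allows at most 3 edited positions of which
at most 2 are gaps ("three mismatches including two gaps", read as: total
edited positions ≤ 3, of which gap positions ≤ 2), candidates are found
by the pigeonhole principle (one of four
exact 25 bp chunks must match), and each read is credited to the single
cluster containing its best match, ties to the larger cluster. Enrichment
per cluster is (ChIP read fraction)/(input read fraction), normalized by
the mean ratio over negative-control clusters (rDNA and a telomeric/
subtelomeric satellite in the real design). The normalization does more
than calibrate units: a family enriched f-fold depresses every other
family's ChIP fraction by the factor 1/(1 + gp·(f−1)), and dividing by
control folds cancels this compositional shift exactly in expectation —
simulated folds {1, 2, 5, 10} are recovered within 3 binomial SE. The
reported SE propagates both fractions' binomial errors on the fold scale;
the control estimate's own error is not propagated (controls are chosen
to be well-populated).

## Comparative analysis

Reads from ≥2 species are tagged with sample codes and pooled into one
clustering run; per-species GP of a cluster is normalized within species
(so one species' depth cannot distort another's proportions — asserted as
an invariant). A species is called present in a cluster at
max(5 reads, 0.0005% of its reads): there is no standard convention for
the absence/presence call in this kind of analysis, and the two-part floor
suppresses cross-contamination artifacts while staying sensitive at
realistic depths. Patterns (e.g. `A+B`, `B`) are derived from presence
calls only. Genome-size arithmetic uses the flow-cytometry ratio formula
(object G1 fluorescence / standard G1 fluorescence × standard size) and
reports fold ratios at one decimal, half-up.

## RT-domain phylogenetics

Each candidate LTR family is represented by the contig whose six-frame
translation best locally aligns (BLOSUM62, gap −11/−1) to a reference RT
peptide set; the aligned peptide segment is extracted, and families whose
best score stays below 60 are dropped (satellites and short fragments
carry no RT signal). Reference profile searches (PSSM-style) are
approximated by pairwise similarity to user-supplied reference peptides;
this is coarser than profile scoring but requires no external databases.
The multiple alignment is a deterministic center-star progressive
alignment (center = highest summed pairwise score; once-a-gap-always-a-gap
merge) — adequate for short conserved RT segments, not a general MSA.
Distances are p-distances with pairwise gap deletion; model-corrected
distances are deliberately not used (p-distance is the default of the
classic NJ tools for peptides, and is oracle-checkable). The NJ
implementation is the classical Saitou–Nei algorithm with a deterministic
tie-break (smallest minimum-descendant-leaf label pair) and negative
branch lengths clamped to zero; it is validated against additive-matrix
recovery, an exhaustive least-squares topology search, and scikit-bio's
independent implementation. Bootstrap support resamples alignment columns
(default 100 replicates, seeded); a replicate pair with no comparable
columns is assigned the maximal p-distance 1. Clade labels transfer from
the nearest reference leaf by tree path length.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions
every recovery claim is made under. Genomes are built from planted blocks
— dispersed family copies (independent substitutions at `divergence`, no
indels, so truth GP stays exact bookkeeping), head-to-tail satellite
arrays with Bernoulli-interspersed deletion-variant monomers, and i.i.d.
uniform background (single-copy sequence must not form clusters). Blocks
are separated by at least `min_gap` (200 bp) of background: without the
floor, two blocks occasionally land nearly adjacent and read chains
across the sliver of background fuse unrelated families. Reads are 100 bp
pairs with normal insert sizes (300 ± 30 by default), uniform strands,
uniform positions, per-base substitution errors, and constant quality;
each read is truth-labeled with the family covering ≥50% of its bases.
ChIP sets sample the target family's bases at `chip_enrichment_fold`
times the background density, with the non-enriched branch drawn from
non-family coordinates only so that the two branches partition the genome
(sampling the whole genome in the uniform branch double-counts the target
and biases fold 1 to ~2). Everything is deterministic under the
simulation seeds; fixed seed means byte-identical FASTQ.

**What the generator does not emulate** — and therefore what passing
tests do not demonstrate about real data: realistic quality profiles and
indel sequencing errors; PCR duplicates; nested/fragmented insertions and
shared domains between families (which blur real cluster boundaries);
higher-order satellite structure; organelle genomes as genuine sequence
(organelle elimination is tested with planted references); library
incompleteness (annotation recall is bounded by the supplied FASTA).

## Problem sizes

The test and acceptance simulations are sized for a single CPU: cluster
recovery uses 8 families (600 bp templates, GP 5–9%) in a 1.2 Mb genome
at exactly 0.5× raw base coverage (6,000 reads) — large enough that
3-sigma binomial sampling noise on a family's read count (~17% relative)
sits inside the ±20% recovery band; the variant study uses a 250 kb
genome that is 45% satellite (~735 monomer copies) at 4× coverage so a 1%
variant has enough junction-spanning reads to clear the 5-read support
floor; ChIP recovery uses 200 kb genomes, 3,000-read sets and 20 seeded
runs. Satellite proportions that high are not meant to be realistic
genome compositions; they are the desk-scale route to adequate copy
numbers for the statistics being tested.

## Known limitations

Single-linkage clustering both fragments (template coverage gaps) and
over-merges (boundary chaining) near its operating limits; the detailed
threshold and the generator's spacer keep the tested regimes away from
those limits, but real low-coverage data sits closer to them. The ChIP
matcher's ≤3-edit contract makes mapping sensitivity fall steeply with
family divergence above ~1%; enrichment ratios are robust to this
(sensitivity cancels between ChIP and input) but per-cluster fractions
are conservative. The center-star MSA and pairwise RT scoring are
deliberate simplifications of profile-based practice. The variant
detector only models single contiguous internal deletions — the form the
102 bp variant takes — not insertions or multi-segment rearrangements.
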