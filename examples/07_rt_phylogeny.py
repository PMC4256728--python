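"""Neighbor-joining phylogeny of retroelement RT domains with bootstrap.

Each LTR family is represented by the contig whose six-frame translation
scores best against a reference set of reverse-transcriptase peptides;
the extracted peptides are progressively aligned, p-distances computed
with pairwise gap deletion, and an unrooted NJ tree built with bootstrap
supports from 100 column resamples. Family leaves are then assigned to
the clade of their nearest reference leaf.
"""

import numpy as np

from repeatscape import (
    assign_clades,
    bootstrap_support,
    pairwise_distances,
    progressive_align,
    select_rt_representative,
)
from repeatscape.clustering import Contig
from repeatscape._dna import random_dna

CODONS = {a: c for a, c in zip(
    "ACDEFGHIKLMNPQRSTVWY",
    ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTT",
     "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT"])}

# two reference RT peptides standing for distinct clades, plus mutated
# family copies of each (simulating conserved RT domains inside contigs)
rng = np.random.default_rng(44)
ref_copia = "MGLTDKQVLELAWENIRQAGGKYVPRGVNHLVSKLHGAEIV"
ref_gypsy = "MRPISDKQWEAFSTHIVDNFKGNPMTYDELVKRWPGAEIIV"
aa = list("ACDEFGHIKLMNPQRSTVWY")


def mutate_pep(pep, n):
    out = list(pep)
    for pos in rng.choice(len(pep), size=n, replace=False):
        out[pos] = aa[rng.integers(0, 20)]
    return "".join(out)


family_contigs = {}
for i, (ref, tag) in enumerate([(ref_copia, "cop"), (ref_copia, "cop"),
                                (ref_gypsy, "gyp"), (ref_gypsy, "gyp")]):
    pep = mutate_pep(ref, 4 + i)
    dna = "".join(CODONS.get(a, "GCT") for a in pep)
    contig = Contig(f"CL{i + 1}c1", random_dna(rng, 60) + dna + random_dna(rng, 60), 20)
    family_contigs[f"CL{i + 1}_{tag}"] = [contig]

refs = [("Tos17_ref", ref_copia), ("Tekay_ref", ref_gypsy)]
reps, dropped = select_rt_representative(family_contigs, refs)
print(f"selected RT representatives for {len(reps)} families "
      f"(dropped: {dropped or 'none'})")

peptides = [(fid, rep.rt_peptide) for fid, rep in sorted(reps.items())] + refs
aligned = progressive_align(peptides)
dm = pairwise_distances(aligned)
tree = bootstrap_support(aligned, n_replicates=100, seed=45)
print("\nNJ tree (bootstrap % on internal nodes):")
print(tree.newick(with_support=True))
clades = assign_clades(tree, {"Tos17_ref": "Ty1/Copia-like",
                              "Tekay_ref": "Ty3/Gypsy-like"})
print("\nclade assignment by nearest reference leaf:")
for fam, clade in sorted(clades.items()):
    print(f"  {fam}: {clade}")
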