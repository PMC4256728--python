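"""Cluster annotation against a repeat library and the superfamily table.

Clusters are classified by aligning their assembled contigs to a reference
repeat library (identity > 70%, query coverage > 50%, both strict);
organelle-matching clusters are eliminated before totals. The summary
mirrors the standard per-superfamily proportion table with retroelement
and DNA-transposon subtotals.
"""

from repeatscape import (
    ClusteringConfig,
    GenomeSpec,
    ReadSimSpec,
    RepeatFamilySpec,
    annotate_cluster,
    assemble_cluster_contigs,
    build_similarity_graph,
    eliminate_organelle_clusters,
    partition_graph,
    simulate_genome,
    simulate_reads,
    summarize_superfamilies,
)

families = [
    RepeatFamilySpec("COPIA1", "LTR_copia", 800, 0.08, divergence=0.01),
    RepeatFamilySpec("GYPSY1", "LTR_gypsy", 800, 0.06, divergence=0.01),
    RepeatFamilySpec("PLASTID1", "rDNA", 700, 0.03, divergence=0.005),
]
genome = simulate_genome(GenomeSpec("CL", 250_000, families, seed=8))
# library entries use the id#Superfamily naming convention; the "plastid"
# family doubles as the organelle reference to demonstrate elimination
library = [
    ("COPIA1", "Ty1/Copia", genome.templates["COPIA1"]),
    ("GYPSY1", "Ty3/Gypsy", genome.templates["GYPSY1"]),
]
organelle = [("PLASTID1", "Organelle", genome.templates["PLASTID1"])]

pairs, _ = simulate_reads(genome, ReadSimSpec(n_pairs=1200, error_rate=0.005, seed=9))
reads = [r for p in pairs for r in p]
config = ClusteringConfig(detail_threshold=0.005)
edges = build_similarity_graph(reads, config)
clusters = partition_graph(edges, reads, config)
reads_by_id = {r.read_id: r for r in reads}
for c in clusters:
    if c.detailed:
        c.contigs = assemble_cluster_contigs(c, reads_by_id, edges)

kept, removed = eliminate_organelle_clusters(clusters, organelle)
print(f"organelle elimination removed {len(removed)} cluster(s): "
      f"{[c.cluster_id for c in removed]}")
for c in kept:
    if c.detailed:
        annotate_cluster(c, library)

table = summarize_superfamilies(kept, species_code="CL")
print("\nsuperfamily summary (GP % of analyzed reads):")
print(table[table.CL > 0].to_string())
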