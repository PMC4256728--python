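"""Sequencing throughput, coverage, and flow-cytometry genome sizing.

Reproduces the bookkeeping used for low-coverage survey sequencing of two
Coix genomes: total read length in Mb, fold coverage (total read length
over twice the 1C size), the flow-cytometry size estimate, and the fold
ratio between the two genomes.
"""

from repeatscape import FlowSample, compute_sequencing_stats
from repeatscape.comparative import estimate_genome_size, genome_size_ratio

for species, n_reads, genome_mb in (
    ("C. lacryma-jobi", 61_869_688, 1684),
    ("C. aquatica HG", 128_853_294, 2335),
):
    s = compute_sequencing_stats(n_reads, read_length=100, genome_size_mb=genome_mb)
    print(
        f"{species:18s} {s.n_reads:>12,d} reads  "
        f"{s.total_read_length_mb:>9.2f} Mb  {s.coverage:.2f}x coverage"
    )

# 1C size from G1-peak fluorescence against a 2300 Mb sizing standard
size = estimate_genome_size(FlowSample(732, 1000, 2300))
print(f"\nflow-cytometry estimate: {size:.1f} Mb "
      "(object G1 / standard G1 x standard size)")
print(f"genome size ratio 2335/1684: {genome_size_ratio(2335, 1684)}-fold")
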