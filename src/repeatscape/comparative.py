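"""Multi-species comparative repeat analysis and genome-size arithmetic.

Pooling reads from several species (each tagged with a sample code) into
one clustering run puts homologous repeat families from different genomes
into the same cluster, so each cluster's per-species read counts measure
that family's genome proportion in every species at once. Clusters are
then classified by their presence pattern — shared across species or
species-specific — which is the comparative readout used to relate
genomes to each other.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from ._dna import round_half_up
from .clustering import (
    ClusteringConfig,
    RepeatCluster,
    build_similarity_graph,
    partition_graph,
)
from .io import ReadRecord


@dataclass(frozen=True)
class FlowSample:
    """Flow-cytometry G1 fluorescence of an object vs a sizing standard."""

    mean_g1_fluorescence_object: float
    mean_g1_fluorescence_standard: float
    standard_genome_size_mb: float

    def __post_init__(self) -> None:
        if (
            self.mean_g1_fluorescence_object <= 0
            or self.mean_g1_fluorescence_standard <= 0
            or self.standard_genome_size_mb <= 0
        ):
            raise ValueError("flow-cytometry values must be positive")


def estimate_genome_size(sample: FlowSample) -> float:
    """1C size in Mb: (object G1 fluorescence / standard G1 fluorescence)
    x standard genome size. Invariant to rescaling both fluorescence means."""
    return (
        sample.mean_g1_fluorescence_object
        / sample.mean_g1_fluorescence_standard
        * sample.standard_genome_size_mb
    )


def genome_size_ratio(size_a_mb: float, size_b_mb: float) -> float:
    """Fold difference of two genome sizes, rounded half-up to 1 decimal."""
    if size_a_mb <= 0 or size_b_mb <= 0:
        raise ValueError("genome sizes must be positive")
    return round_half_up(size_a_mb / size_b_mb, 1)


def comparative_cluster_analysis(
    reads: list[ReadRecord],
    config: ClusteringConfig | None = None,
    presence_min_reads: int = 5,
    presence_min_fraction: float = 0.000005,
    clusters: list[RepeatCluster] | None = None,
) -> pd.DataFrame:
    """Cluster pooled multi-species reads and tabulate per-species GP.

    Every read must carry a species code. Per-species GP of a cluster is
    100 x (cluster reads of that species) / (total reads of that species) —
    normalized within species, so one species' depth cannot distort
    another's proportions. A species is called present in a cluster when
    it contributes at least max(presence_min_reads, presence_min_fraction
    of its reads); the cluster's pattern is the ``+``-joined sorted codes
    of present species. Precomputed ``clusters`` may be supplied to skip
    the clustering step.

    Only detailed clusters are tabulated.
    """
    codes = sorted({r.species_code for r in reads if r.species_code})
    if any(r.species_code is None for r in reads):
        raise ValueError("every read needs a species code for comparative analysis")
    if len(codes) < 2:
        raise ValueError("comparative analysis needs >= 2 species")
    totals = defaultdict(int)
    for r in reads:
        totals[r.species_code] += 1
    if clusters is None:
        config = config or ClusteringConfig()
        edges = build_similarity_graph(reads, config)
        clusters = partition_graph(edges, reads, config)

    species_of = {}
    for r in reads:
        rid = r.read_id
        species_of[rid] = r.species_code
        species_of[f"{r.species_code}|{rid}"] = r.species_code

    rows = []
    for cluster in clusters:
        if not cluster.detailed:
            continue
        counts: dict[str, int] = defaultdict(int)
        for rid in cluster.read_ids:
            counts[species_of[rid]] += 1
        row: dict[str, object] = {
            "cluster_id": cluster.cluster_id,
            "superfamily": cluster.annotation or "Unclassified",
            "n_reads": cluster.n_reads,
        }
        present = []
        for code in codes:
            n = counts.get(code, 0)
            row[f"{code}_reads"] = n
            row[f"{code}_gp"] = 100.0 * n / totals[code]
            floor = max(presence_min_reads, presence_min_fraction * totals[code])
            if n >= floor:
                present.append(code)
        row["pattern"] = "+".join(present)
        rows.append(row)
    return pd.DataFrame(rows)


def pattern_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Cluster counts and per-species GP sums for each presence pattern."""
    if table.empty:
        raise ValueError("comparative table is empty")
    gp_cols = [c for c in table.columns if c.endswith("_gp")]
    grouped = table.groupby("pattern", sort=True)
    out = grouped.agg(
        n_clusters=("cluster_id", "size"), **{c: (c, "sum") for c in gp_cols}
    ).reset_index()
    return out
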