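"""Graph-based repeat clustering of unassembled reads.

The central idea: in low-coverage shotgun data, reads from a repeat family
find each other by sequence similarity even without an assembly. Reads are
vertices; an edge joins two reads whose best overlap alignment passes
identity and overlap-length thresholds; connected groups of reads are
repeat families, and a family's genome proportion (GP) is simply the
percentage of analyzed reads it absorbed.

Candidate read pairs are found by shared k-mers (canonicalized so
reverse-complement overlaps are caught), the relative offset of a pair is
taken as the modal k-mer diagonal, and the implied overlap is verified by
edit-distance alignment (edlib). Clusters are ranked CL1, CL2, ... by
descending read count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import networkx as nx

from ._dna import revcomp
from .io import ReadRecord


@dataclass(frozen=True)
class SimilarityEdge:
    """A verified overlap between two reads.

    ``offset`` is the start of read_b (oriented per ``same_strand``) in
    read_a's coordinates; it is what lets the assembler lay reads out.
    """

    read_a: str
    read_b: str
    identity: float
    overlap_fraction: float
    offset: int
    same_strand: bool


@dataclass
class ClusteringConfig:
    """Similarity-graph thresholds.

    Defaults: 90% identity over >=55% of the shorter read (the canonical
    graph-clustering defaults for 100 bp reads), 17-mer candidate seeding,
    and a detailed-analysis floor of 0.005% of reads per cluster.
    """

    min_identity: float = 90.0
    min_overlap_fraction: float = 0.55
    kmer_length: int = 17
    minimizer_window: int = 8
    detail_threshold: float = 0.00005
    partition_method: str = "connected_components"

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.partition_method not in ("connected_components", "louvain"):
            raise ValueError(f"unknown partition_method {self.partition_method!r}")


@dataclass
class Contig:
    """A consensus sequence assembled from a cluster's reads."""

    contig_id: str
    sequence: str
    n_reads: int


@dataclass
class RepeatCluster:
    """A connected family of mutually similar reads.

    ``genome_proportion`` is 100 x n_reads / total analyzed reads — the
    read-count proxy for the family's share of the genome.
    """

    cluster_id: str
    read_ids: list[str]
    n_reads: int
    genome_proportion: float
    detailed: bool
    contigs: list[Contig] = field(default_factory=list)
    annotation: str | None = None


def _minimizers(seq: str, k: int, w: int):
    """(position, canonical k-mer, forward-is-canonical) minimizers.

    In each window of ``w`` consecutive k-mer start positions, the
    lexicographically smallest canonical k-mer is selected (leftmost on
    ties). Because selection depends only on local sequence, two reads
    sharing a region pick the same minimizers regardless of their relative
    offset — unlike strided sampling, which misses offsets that are not
    stride multiples.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return
    canon: list[tuple[str, bool] | None] = []
    for p in range(n):
        km = seq[p : p + k]
        if "N" in km:
            canon.append(None)
            continue
        rc = revcomp(km)
        canon.append((km, True) if km <= rc else (rc, False))
    selected: set[int] = set()
    for start in range(0, n, max(1, w // 2)):
        window = [(canon[p][0], p) for p in range(start, min(start + w, n)) if canon[p]]
        if window:
            _, p = min(window)
            selected.add(p)
    for p in sorted(selected):
        km, fwd = canon[p]
        yield p, km, fwd


def _candidate_pairs(reads: list[ReadRecord], config: ClusteringConfig):
    """Shared-minimizer candidate pairs with diagonal votes.

    Yields ((i, j), same_strand, offset) for i < j, where offset/strand are
    the modal k-mer diagonal. k-mers are canonicalized (min of forward and
    reverse complement) so both-strand hits land in one bucket.
    """
    k = config.kmer_length
    index: dict[str, list[tuple[int, int, bool]]] = defaultdict(list)
    for idx, r in enumerate(reads):
        for p, km, fwd in _minimizers(r.bases, k, config.minimizer_window):
            index[km].append((idx, p, fwd))

    votes: dict[tuple[int, int], dict[tuple[bool, int], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for entries in index.values():
        if len(entries) < 2:
            continue
        for x in range(len(entries)):
            i, pi, fi = entries[x]
            for y in range(x + 1, len(entries)):
                j, pj, fj = entries[y]
                if i == j:
                    continue
                a, pa, fa = (i, pi, fi) if i < j else (j, pj, fj)
                b, pb, fb = (j, pj, fj) if i < j else (i, pi, fi)
                same = fa == fb
                if same:
                    d = pa - pb
                else:
                    d = pa - (len(reads[b].bases) - k - pb)
                votes[(a, b)][(same, d)] += 1

    for pair, diag_votes in votes.items():
        (same, d), _ = max(
            diag_votes.items(), key=lambda kv: (kv[1], kv[0][0], -abs(kv[0][1]))
        )
        yield pair, same, d


def _verify_overlap(
    a: str, b: str, same_strand: bool, offset: int
) -> tuple[float, float] | None:
    """Align the overlap implied by (same_strand, offset).

    Returns (identity %, overlap fraction of the shorter read), or None for
    an empty overlap.
    """
    b_or = b if same_strand else revcomp(b)
    lo_a, hi_a = max(0, offset), min(len(a), offset + len(b_or))
    if hi_a - lo_a <= 0:
        return None
    sub_a = a[lo_a:hi_a]
    sub_b = b_or[lo_a - offset : hi_a - offset]
    dist = edlib.align(sub_a, sub_b, mode="NW", task="distance")["editDistance"]
    length = max(len(sub_a), len(sub_b))
    identity = 100.0 * (1.0 - dist / length)
    overlap_fraction = length / min(len(a), len(b))
    return identity, overlap_fraction


def build_similarity_graph(
    reads: list[ReadRecord], config: ClusteringConfig | None = None
) -> list[SimilarityEdge]:
    """All verified read-read overlap edges passing the config thresholds."""
    config = config or ClusteringConfig()
    if not reads:
        raise ValueError("no reads supplied")
    edges: list[SimilarityEdge] = []
    for (i, j), same, offset in _candidate_pairs(reads, config):
        res = _verify_overlap(reads[i].bases, reads[j].bases, same, offset)
        if res is None:
            continue
        identity, overlap = res
        if identity >= config.min_identity and overlap >= config.min_overlap_fraction:
            edges.append(
                SimilarityEdge(
                    read_a=reads[i].read_id,
                    read_b=reads[j].read_id,
                    identity=identity,
                    overlap_fraction=overlap,
                    offset=offset,
                    same_strand=same,
                )
            )
    return edges


def partition_graph(
    edges: list[SimilarityEdge],
    reads: list[ReadRecord],
    config: ClusteringConfig | None = None,
) -> list[RepeatCluster]:
    """Partition reads into clusters; every read lands in exactly one.

    Singletons (reads with no passing edge) are kept as size-1 clusters and
    count as non-repetitive. A cluster is ``detailed`` when its read count
    reaches ``detail_threshold`` of all analyzed reads and it has >= 2
    reads. Ranks: read count descending, ties by smallest member read id.
    """
    config = config or ClusteringConfig()
    g = nx.Graph()
    g.add_nodes_from(r.read_id for r in reads)
    g.add_edges_from((e.read_a, e.read_b) for e in edges)
    if config.partition_method == "louvain":
        communities = nx.community.louvain_communities(g, seed=0)
    else:
        communities = list(nx.connected_components(g))
    total = len(reads)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    clusters = []
    for rank, members in enumerate(ordered, start=1):
        n = len(members)
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{rank}",
                read_ids=sorted(members),
                n_reads=n,
                genome_proportion=100.0 * n / total,
                detailed=(n >= 2 and n / total >= config.detail_threshold),
            )
        )
    return clusters


def assemble_cluster_contigs(
    cluster: RepeatCluster,
    reads_by_id: dict[str, ReadRecord],
    edges: list[SimilarityEdge],
) -> list[Contig]:
    """Greedy overlap-layout consensus for one cluster.

    The highest-degree read seeds a coordinate system; edges place the
    remaining reads by breadth-first propagation of (offset, strand), and
    the consensus is a per-column majority vote. Reads the edge set cannot
    reach start further contigs, so each cluster yields >= 1 contig and
    every contig is at least one read long.
    """
    members = set(cluster.read_ids)
    adj: dict[str, list[tuple[str, int, bool]]] = defaultdict(list)
    degree: dict[str, int] = {rid: 0 for rid in cluster.read_ids}
    for e in edges:
        if e.read_a in members and e.read_b in members:
            adj[e.read_a].append((e.read_b, e.offset, e.same_strand))
            la, lb = len(reads_by_id[e.read_a]), len(reads_by_id[e.read_b])
            # invert the placement: a in b's coordinates
            if e.same_strand:
                adj[e.read_b].append((e.read_a, -e.offset, True))
            else:
                adj[e.read_b].append((e.read_a, e.offset + lb - la, False))
            degree[e.read_a] += 1
            degree[e.read_b] += 1

    unplaced = set(cluster.read_ids)
    contigs: list[Contig] = []
    part = 0
    while unplaced:
        seed = max(unplaced, key=lambda rid: (degree[rid], rid))
        placement: dict[str, tuple[int, bool]] = {seed: (0, True)}
        queue = [seed]
        unplaced.discard(seed)
        while queue:
            cur = queue.pop(0)
            pos_c, fwd_c = placement[cur]
            lc = len(reads_by_id[cur])
            for nb, offset, same in adj[cur]:
                if nb in placement:
                    continue
                lb = len(reads_by_id[nb])
                if fwd_c:
                    pos_b = pos_c + offset
                    fwd_b = same
                else:
                    pos_b = pos_c + (lc - (offset + lb))
                    fwd_b = not same
                placement[nb] = (pos_b, fwd_b)
                unplaced.discard(nb)
                queue.append(nb)
        base = min(pos for pos, _ in placement.values())
        span = max(pos + len(reads_by_id[rid]) for rid, (pos, _) in placement.items())
        ncols = span - base
        counts = [defaultdict(int) for _ in range(ncols)]
        for rid, (pos, fwd) in placement.items():
            seq = reads_by_id[rid].bases
            if not fwd:
                seq = revcomp(seq)
            for off, ch in enumerate(seq):
                counts[pos - base + off][ch] += 1
        consensus = "".join(
            max(sorted(col), key=col.get) if col else "N" for col in counts
        )
        part += 1
        contigs.append(
            Contig(
                contig_id=f"{cluster.cluster_id}c{part}",
                sequence=consensus,
                n_reads=len(placement),
            )
        )
    contigs.sort(key=lambda c: (-c.n_reads, c.contig_id))
    return contigs


def total_repeat_fraction(
    clusters: list[RepeatCluster], min_reads: int = 2
) -> float:
    """Total repetitive GP: summed proportions of detailed clusters.

    Call after organelle elimination; singleton reads count as
    non-repetitive.
    """
    return sum(
        c.genome_proportion
        for c in clusters
        if c.detailed and c.n_reads >= min_reads
    )
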