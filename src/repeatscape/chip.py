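"""Reference-free ChIP-seq enrichment over repeat clusters.

Without an assembled genome, ChIP reads are identified by matching them
against the genomic reads that make up each repeat cluster: a ChIP read
counts for a cluster if it aligns to one of the cluster's member reads
with at most three edited positions, of which at most two may be gaps, and
each read is credited to the single cluster holding its best match.
Enrichment is the ChIP/input ratio of per-cluster read fractions,
normalized by the mean ratio over negative-control clusters (families with
no expected CenH3 association), which also cancels the compositional shift
a strong enrichment imposes on every other family's fraction.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass

import edlib

from ._dna import revcomp
from .clustering import RepeatCluster
from .io import ReadRecord
from .satellite import SatelliteProfile, detect_monomer_variants

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ChipMapConfig:
    """Matching contract: <=3 edited positions total, <=2 of them gaps."""

    max_mismatches: int = 3
    max_gaps: int = 2

    def __post_init__(self) -> None:
        if self.max_gaps > self.max_mismatches:
            raise ValueError("max_gaps cannot exceed max_mismatches")


@dataclass
class EnrichmentResult:
    cluster_id: str
    chip_fraction: float
    input_fraction: float
    fold: float | None
    normalized_fold: float | None
    se: float | None


def _gap_positions(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "ID")


def map_reads_to_clusters(
    reads: list[ReadRecord],
    clusters: list[RepeatCluster],
    genomic_reads_by_id: dict[str, ReadRecord],
    config: ChipMapConfig | None = None,
) -> dict[str, tuple[str, int]]:
    """Assign each ChIP read to at most one cluster.

    Returns read_id -> (cluster_id, edit distance). Candidate genomic
    reads are found by the pigeonhole principle: a read within
    ``max_mismatches`` edits of a target must share one of its
    (max_mismatches + 1) non-overlapping chunks exactly, so an exact-chunk
    index over the cluster members finds every admissible hit. Each
    candidate is verified by global alignment; a hit needs total edits
    <= max_mismatches with gap positions <= max_gaps. Ties across clusters
    go to the larger cluster (lower rank number); the rule is
    deterministic and order-independent.
    """
    config = config or ChipMapConfig()
    rank_of = {c.cluster_id: i for i, c in enumerate(clusters)}
    cluster_of: dict[str, str] = {}
    member_ids: list[str] = []
    for c in clusters:
        for rid in c.read_ids:
            cluster_of[rid] = c.cluster_id
            member_ids.append(rid)
    if not member_ids:
        return {}

    n_chunks = config.max_mismatches + 1
    min_len = min(len(genomic_reads_by_id[rid]) for rid in member_ids)
    chunk = max(8, min_len // n_chunks)
    index: dict[str, list[str]] = defaultdict(list)
    for rid in member_ids:
        seq = genomic_reads_by_id[rid].bases
        for p in range(0, len(seq) - chunk + 1):
            index[seq[p : p + chunk]].append(rid)

    assignments: dict[str, tuple[str, int]] = {}
    for read in reads:
        best: tuple[int, int, str] | None = None  # (distance, rank, cluster_id)
        seen: set[str] = set()
        for seq in (read.bases, revcomp(read.bases)):
            candidates: set[str] = set()
            for p in range(0, len(seq) - chunk + 1, chunk):
                candidates.update(index.get(seq[p : p + chunk], ()))
            for rid in candidates:
                key = rid + ("+" if seq is read.bases else "-")
                if key in seen:
                    continue
                seen.add(key)
                res = edlib.align(
                    seq,
                    genomic_reads_by_id[rid].bases,
                    mode="NW",
                    task="path",
                    k=config.max_mismatches,
                )
                d = res["editDistance"]
                if d < 0 or d > config.max_mismatches:
                    continue
                if _gap_positions(res["cigar"] or "") > config.max_gaps:
                    continue
                cid = cluster_of[rid]
                cand = (d, rank_of[cid], cid)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            assignments[read.read_id] = (best[2], best[0])
    return assignments


def compute_enrichment(
    assignments_chip: dict[str, tuple[str, int]],
    assignments_input: dict[str, tuple[str, int]],
    n_chip_total: int,
    n_input_total: int,
    clusters: list[RepeatCluster],
    negative_controls: list[str],
) -> dict[str, EnrichmentResult]:
    """Input-normalized fold enrichment per cluster.

    fold = (ChIP read fraction) / (input read fraction); normalized_fold
    divides by the mean fold across the negative-control clusters. The
    reported standard error propagates the binomial errors of both
    fractions on the fold scale.
    """
    if not assignments_chip or not assignments_input:
        raise ValueError("both assignment sets must be nonempty")
    counts_chip: dict[str, int] = defaultdict(int)
    counts_input: dict[str, int] = defaultdict(int)
    for cid, _ in assignments_chip.values():
        counts_chip[cid] += 1
    for cid, _ in assignments_input.values():
        counts_input[cid] += 1

    folds: dict[str, float | None] = {}
    results: dict[str, EnrichmentResult] = {}
    for c in clusters:
        fc = counts_chip.get(c.cluster_id, 0) / n_chip_total
        fi = counts_input.get(c.cluster_id, 0) / n_input_total
        folds[c.cluster_id] = (fc / fi) if fi > 0 else None
        results[c.cluster_id] = EnrichmentResult(
            c.cluster_id, fc, fi, folds[c.cluster_id], None, None
        )

    control_folds = [
        folds[cid] for cid in negative_controls if folds.get(cid) is not None
    ]
    if not control_folds:
        raise ValueError("all negative-control clusters lack input reads")
    norm = sum(control_folds) / len(control_folds)

    for c in clusters:
        r = results[c.cluster_id]
        if r.fold is None:
            continue
        r.normalized_fold = r.fold / norm
        nc = counts_chip.get(c.cluster_id, 0)
        ni = counts_input.get(c.cluster_id, 0)
        if nc > 0 and ni > 0:
            rel = math.sqrt(
                (1 - r.chip_fraction) / nc + (1 - r.input_fraction) / ni
            )
            r.se = r.normalized_fold * rel
    return results


def chip_satellite_variant_share(
    assignments_chip: dict[str, tuple[str, int]],
    chip_reads_by_id: dict[str, ReadRecord],
    profile: SatelliteProfile,
    genomic_family_reads: list[ReadRecord] | None = None,
    min_support: int = 5,
) -> dict[str, float]:
    """Share of a satellite's variant monomer in the ChIP read set.

    Quantifies the variant among ChIP reads assigned to the satellite
    cluster, and (when the cluster's genomic reads are given) the
    genome-wide analogue, both as estimated percent of monomer copies.
    Returns zeros for the ChIP share when no assigned read supports the
    variant.
    """
    family_chip = [
        chip_reads_by_id[rid]
        for rid, (cid, _) in assignments_chip.items()
        if cid == profile.cluster_id and rid in chip_reads_by_id
    ]
    if not family_chip:
        raise ValueError(
            f"no ChIP reads assigned to satellite cluster {profile.cluster_id}"
        )
    probe = SatelliteProfile(
        cluster_id=profile.cluster_id,
        period=profile.period,
        consensus_monomer=profile.consensus_monomer,
        array_span=profile.array_span,
    )
    chip_variants = detect_monomer_variants(probe, family_chip, min_support=min_support)
    out = {
        "chip_variant_pct": chip_variants[0].family_fraction if chip_variants else 0.0,
        "chip_read_pct": chip_variants[0].read_fraction if chip_variants else 0.0,
        "n_chip_family_reads": float(len(family_chip)),
    }
    if genomic_family_reads:
        probe_g = SatelliteProfile(
            cluster_id=profile.cluster_id,
            period=profile.period,
            consensus_monomer=profile.consensus_monomer,
            array_span=profile.array_span,
        )
        gvars = detect_monomer_variants(
            probe_g, genomic_family_reads, min_support=min_support
        )
        out["genomic_variant_pct"] = gvars[0].family_fraction if gvars else 0.0
    return out
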