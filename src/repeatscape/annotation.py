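"""Cluster and read annotation against reference repeat libraries.

Clusters are classified by aligning their contigs to a user-supplied
repeat library (FASTA records named ``id#Superfamily``, the RepeatMasker
naming convention); a hit counts only above 70% identity and 50% query
coverage, both strict. The same screen drives organelle-cluster
elimination (against a plastid/mitochondrial FASTA) and masking-style
per-read annotation used for cross-genus comparisons.

"Coverage" here is query coverage — the fraction of the contig or read
that aligns — which is the reading under which short queries against long
references behave sensibly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import pandas as pd

from ._dna import revcomp, round_half_up
from .clustering import RepeatCluster
from .io import ReadRecord
from .satellite import find_satellite_monomer

SUPERFAMILIES = (
    "Ty1/Copia",
    "Ty3/Gypsy",
    "Unclassified LTR",
    "LINE/SINE",
    "hAT",
    "Mutator",
    "RC/Helitron",
    "En-Spm",
    "PIF-Harbinger",
    "Tc1-Mariner",
    "Other",
    "rDNA",
    "Satellite",
    "Organelle",
    "Unclassified",
)

RETROELEMENT_ROWS = ("Ty1/Copia", "Ty3/Gypsy", "Unclassified LTR", "LINE/SINE")
TRANSPOSON_ROWS = (
    "hAT",
    "Mutator",
    "RC/Helitron",
    "En-Spm",
    "PIF-Harbinger",
    "Tc1-Mariner",
    "Other",
)


@dataclass(frozen=True)
class AnnotationHit:
    query_id: str
    library_id: str
    identity: float
    query_coverage: float
    superfamily: str


@dataclass
class AnnotationConfig:
    """Identity/coverage screen for library hits (strict > on both)."""

    min_identity: float = 70.0
    min_coverage: float = 50.0

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not (0 <= v <= 100):
                raise ValueError("thresholds must be within [0, 100]")


def parse_library(records: list[tuple[str, str]]) -> list[tuple[str, str, str]]:
    """(library_id, superfamily, sequence) from FASTA records.

    The superfamily is taken from an ``id#Superfamily`` name; records
    without one fall back to ``Unclassified``.
    """
    out = []
    for name, seq in records:
        ident = name.split()[0]
        if "#" in ident:
            lib_id, superfamily = ident.split("#", 1)
        else:
            lib_id, superfamily = ident, "Unclassified"
        out.append((lib_id, superfamily, seq))
    return out


def _align_infix(short: str, long: str) -> int:
    """Best edit distance of `short` (either strand) inside `long`."""
    best = -1
    for seq in (short, revcomp(short)):
        d = edlib.align(seq, long, mode="HW", task="distance")["editDistance"]
        if d >= 0 and (best < 0 or d < best):
            best = d
    return best


def best_hit(
    query_id: str,
    query: str,
    library: list[tuple[str, str, str]],
    config: AnnotationConfig | None = None,
) -> AnnotationHit | None:
    """Best passing library hit for one contig or read, or None.

    The shorter sequence of each (query, library) pair is aligned as an
    infix of the longer on both strands; identity is computed over the
    shorter, and query coverage is the aligned fraction of the query.
    """
    config = config or AnnotationConfig()
    best: AnnotationHit | None = None
    for lib_id, superfamily, lib_seq in library:
        if not lib_seq or not query:
            continue
        if len(query) <= len(lib_seq):
            d = _align_infix(query, lib_seq)
            if d < 0:
                continue
            identity = 100.0 * (1 - d / len(query))
            coverage = 100.0
        else:
            d = _align_infix(lib_seq, query)
            if d < 0:
                continue
            identity = 100.0 * (1 - d / len(lib_seq))
            coverage = 100.0 * len(lib_seq) / len(query)
        if identity > config.min_identity and coverage > config.min_coverage:
            cand = AnnotationHit(query_id, lib_id, identity, coverage, superfamily)
            if best is None or (cand.identity, cand.query_coverage) > (
                best.identity,
                best.query_coverage,
            ):
                best = cand
    return best


def annotate_cluster(
    cluster: RepeatCluster,
    library: list[tuple[str, str, str]],
    config: AnnotationConfig | None = None,
    check_tandem: bool = True,
) -> RepeatCluster:
    """Assign a superfamily to a cluster from its contigs' best hits.

    Each contig votes with its read support for the superfamily of its
    best passing hit; the plurality wins, ties conservatively resolve to
    Unclassified. A cluster with no passing hit but clear tandem structure
    in a contig is called Satellite; otherwise Unclassified.
    """
    config = config or AnnotationConfig()
    votes: dict[str, int] = defaultdict(int)
    for contig in cluster.contigs:
        hit = best_hit(contig.contig_id, contig.sequence, library, config)
        if hit is not None:
            votes[hit.superfamily] += contig.n_reads
    if votes:
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            cluster.annotation = "Unclassified"
        else:
            cluster.annotation = ranked[0][0]
        return cluster
    if check_tandem and any(
        find_satellite_monomer(c.sequence) is not None for c in cluster.contigs
    ):
        cluster.annotation = "Satellite"
    else:
        cluster.annotation = "Unclassified"
    return cluster


def eliminate_organelle_clusters(
    clusters: list[RepeatCluster],
    organelle_library: list[tuple[str, str, str]],
    config: AnnotationConfig | None = None,
) -> tuple[list[RepeatCluster], list[RepeatCluster]]:
    """Drop clusters whose contigs hit the organelle reference.

    Returns (kept, removed); surviving clusters are untouched. Run before
    totalling repeat proportions so plastid/mitochondrial reads do not
    inflate the repeat fraction.
    """
    if not organelle_library:
        raise ValueError("organelle library is empty")
    config = config or AnnotationConfig()
    kept, removed = [], []
    for cluster in clusters:
        hit = None
        for contig in cluster.contigs:
            hit = best_hit(contig.contig_id, contig.sequence, organelle_library, config)
            if hit is not None:
                break
        if hit is not None:
            cluster.annotation = "Organelle"
            removed.append(cluster)
        else:
            kept.append(cluster)
    return kept, removed


def superfamily_table(columns: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Superfamily summary with subtotals, one column per species.

    ``columns`` maps species code -> {superfamily row label: GP %}. Rows:
    the retroelement block (Ty1/Copia, Ty3/Gypsy, Unclassified LTR,
    LINE/SINE) with its subtotal, the DNA-transposon block with its
    subtotal, rDNA, Satellite, Unclassified, and the grand total. All
    values are percentages of analyzed reads rounded half-up to 2
    decimals; subtotals are exact sums of their displayed rows.
    """
    index = (
        ["Retrotransposon"]
        + list(RETROELEMENT_ROWS)
        + ["Transposon"]
        + list(TRANSPOSON_ROWS)
        + ["rDNA", "Satellite", "Unclassified", "Total"]
    )
    table = pd.DataFrame(index=index, columns=list(columns), dtype=float)
    for code, gp in columns.items():
        vals = {label: round_half_up(gp.get(label, 0.0), 2) for label in SUPERFAMILIES}
        retro = round_half_up(sum(vals[r] for r in RETROELEMENT_ROWS), 2)
        transposon = round_half_up(sum(vals[r] for r in TRANSPOSON_ROWS), 2)
        total = round_half_up(
            retro + transposon + vals["rDNA"] + vals["Satellite"] + vals["Unclassified"],
            2,
        )
        for label in RETROELEMENT_ROWS + TRANSPOSON_ROWS:
            table.loc[label, code] = vals[label]
        table.loc["Retrotransposon", code] = retro
        table.loc["Transposon", code] = transposon
        table.loc["rDNA", code] = vals["rDNA"]
        table.loc["Satellite", code] = vals["Satellite"]
        table.loc["Unclassified", code] = vals["Unclassified"]
        table.loc["Total", code] = total
    return table


def summarize_superfamilies(
    clusters: list[RepeatCluster], species_code: str = "sample"
) -> pd.DataFrame:
    """Superfamily table from annotated clusters (detailed clusters only)."""
    gp: dict[str, float] = defaultdict(float)
    for c in clusters:
        if not c.detailed:
            continue
        label = c.annotation or "Unclassified"
        gp[label] += c.genome_proportion
    return superfamily_table({species_code: dict(gp)})


def annotate_reads_by_reference(
    reads: list[ReadRecord],
    library: list[tuple[str, str, str]],
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Masking-style per-read annotation: best passing family per read.

    Returns a table (family, n_reads, pct_reads) over the library families
    plus an ``unassigned`` row; used to compare annotations produced by
    two different reference genomes.
    """
    if not library:
        raise ValueError("reference library is empty")
    config = config or AnnotationConfig()
    counts: dict[str, int] = defaultdict(int)
    for read in reads:
        hit = best_hit(read.read_id, read.bases, library, config)
        counts[hit.library_id if hit else "unassigned"] += 1
    total = max(1, len(reads))
    rows = [
        {"family": fam, "n_reads": n, "pct_reads": round_half_up(100.0 * n / total, 2)}
        for fam, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["family", "n_reads", "pct_reads"])
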