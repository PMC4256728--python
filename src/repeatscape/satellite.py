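"""Tandem-repeat monomer detection and monomer-variant quantification.

Satellite DNA shows up in cluster contigs as head-to-tail repetition of a
monomer (e.g. a 153 bp centromeric unit). The detector finds the monomer
period from the recurrence distances of exact 12-mers, builds a consensus
by columnwise majority vote, and reports it in a canonical form that is
invariant to rotation and strand. Variant monomers — copies carrying a
consistent internal deletion, such as a 102 bp form of a 153 bp unit — are
recovered from reads whose alignment to the tandem consensus shows the
same deleted segment.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from ._dna import canonical_monomer, revcomp
from .io import ReadRecord


@dataclass
class MonomerVariant:
    """A shortened monomer form defined by one internal deletion."""

    length: int
    deleted_start: int
    deleted_segment: str
    n_support: int
    read_fraction: float
    family_fraction: float


@dataclass
class SatelliteProfile:
    """A tandem family's period, canonical consensus and variants."""

    cluster_id: str
    period: int
    consensus_monomer: str
    array_span: int
    variants: list[MonomerVariant] = field(default_factory=list)


def _fold_consensus(seq: str, period: int) -> str:
    """Majority-vote consensus of seq folded at ``period``.

    Ties go to the alphabetically first base for determinism.
    """
    cols: list[Counter] = [Counter() for _ in range(period)]
    for i, ch in enumerate(seq):
        cols[i % period][ch] += 1
    return "".join(
        min(sorted(c), key=lambda b: (-c[b], b)) if c else "A" for c in cols
    )


def _divisors(n: int) -> list[int]:
    out = set()
    for d in range(1, int(math.isqrt(n)) + 1):
        if n % d == 0:
            out.update((d, n // d))
    return sorted(out)


def find_satellite_monomer(
    contig: str,
    kmer: int = 12,
    small_period_max: int = 23,
    min_explained: float = 0.80,
) -> tuple[int, str] | None:
    """Find the smallest tandem period in a contig, or None.

    Candidate periods come from two sources: a direct scan of all small
    periods (< 24 bp, below the k-mer resolution) and the modal recurrence
    distances between repeated 12-mers (plus their divisors, so a
    higher-order mode cannot hide the true unit). A candidate qualifies by
    lag self-identity: the fraction of positions i with
    contig[i] == contig[i + p] must reach ``min_explained``. This measures
    copy-to-copy identity directly and, unlike a global fold consensus,
    survives the occasional phase jump that a deletion-variant copy
    introduces into a long array. The smallest qualifying period wins; the
    consensus is voted over the most phase-coherent window and returned
    canonically (lexicographically minimal rotation of the smaller
    strand), making the result rotation- and strand-invariant.

    Periods longer than half the contig (down to one full copy plus a
    partial second) are detectable when backed by a well-supported k-mer
    recurrence distance: assembled contigs of a long-monomer satellite
    often wrap at little more than one unit.
    """
    import numpy as np

    contig = contig.upper()
    n = len(contig)
    if n < 4:
        return None
    max_period = n - kmer
    arr = np.frombuffer(contig.encode(), dtype=np.uint8)

    candidates = set(p for p in range(2, min(small_period_max, n // 2) + 1))
    long_ok: set[int] = set()
    positions: dict[str, int] = {}
    dist_votes: Counter = Counter()
    for p in range(n - kmer + 1):
        km = contig[p : p + kmer]
        if "N" in km:
            continue
        if km in positions:
            dist_votes[p - positions[km]] += 1
        positions[km] = p
    for d, count in dist_votes.most_common(8):
        if count < 2:
            break
        for j in (d - 1, d, d + 1):
            if small_period_max < j <= max_period:
                candidates.add(j)
                if count >= 3:
                    long_ok.add(j)
            for div in _divisors(j):
                if small_period_max < div <= max_period:
                    candidates.add(div)
                    if count >= 3:
                        long_ok.add(div)

    for p in sorted(candidates):
        if n - p < max(kmer, 10):
            continue
        if p > n // 2 and p not in long_ok:
            continue
        match = arr[:-p] == arr[p:]
        if float(match.mean()) < min_explained:
            continue
        # consensus from the most phase-coherent stretch (dodges the local
        # disruption around any variant-copy phase jump)
        m = match.astype(np.float64)
        w = min(len(m), max(2 * p, 600))
        if len(m) > w:
            sums = np.convolve(m, np.ones(w), mode="valid")
            s = int(np.argmax(sums))
        else:
            s = 0
        region = contig[s : s + w + p]
        consensus = _fold_consensus(region, p)
        return p, canonical_monomer(consensus)
    return None


def profile_cluster(cluster, **kwargs) -> SatelliteProfile | None:
    """Profile a cluster's tandem structure from its longest-supported contig."""
    best = None
    for contig in cluster.contigs:
        res = find_satellite_monomer(contig.sequence, **kwargs)
        if res is None:
            continue
        period, consensus = res
        span = len(contig.sequence)
        if best is None or span > best[2]:
            best = (period, consensus, span)
    if best is None:
        return None
    period, consensus, span = best
    return SatelliteProfile(
        cluster_id=cluster.cluster_id,
        period=period,
        consensus_monomer=consensus,
        array_span=span,
    )


def _semiglobal_dp(read: str, ref: str):
    """Edit-distance DP of `read` vs `ref` with a free start in the reference.

    Returns F with F[i][t] = min edits aligning read[:i] so that the
    alignment ends at reference position t (rows vectorized with numpy).
    """
    import numpy as np

    L, M = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    F = np.empty((L + 1, M + 1), dtype=np.int32)
    F[0] = 0
    offsets = np.arange(M + 1)
    for i in range(1, L + 1):
        prev = F[i - 1]
        mis = (ref_arr != read_arr[i - 1]).astype(np.int32)
        cand = np.empty(M + 1, dtype=np.int32)
        cand[0] = i
        cand[1:] = np.minimum(prev[:-1] + mis, prev[1:] + 1)
        # left-to-right gap closure: F[i][t] = min_k<=t cand[k] + (t - k)
        F[i] = np.minimum(cand, np.minimum.accumulate(cand - offsets) + offsets)
    return F


def _split_deletion(
    bases: str,
    reference: str,
    period: int,
    anchor: int,
    min_del: int,
    max_split_cost: int,
    min_margin: int,
):
    """One-jump spliced alignment of a read against a tandem consensus.

    A read spanning an internal monomer deletion cannot reveal it through a
    single cheapest edit path: for deletions comparable to the read length
    it is always cheaper to misalign the shorter flank as substitutions
    than to pay one gap position per deleted base. Instead the read prefix
    and suffix are aligned semi-globally and one free jump of length >=
    ``min_del`` is allowed between them; the jump length modulo the period
    is the net deleted segment (a whole-monomer jump is no variant at all).

    Returns (deletion start in monomer coordinates, net deletion length)
    or None. The split must be anchored by ``anchor`` read bases on both
    sides, cost at most ``max_split_cost``, and undercut the jump-free
    alignment by ``min_margin`` edits.
    """
    import numpy as np

    # a junction read's jump-free cost is at most ~0.75 x its shorter
    # flank; anything above this bound is wrong-strand or foreign sequence
    max_full = int(0.8 * len(bases) / 2) + 4
    best = None  # (split_cost, t1, t2)
    for seq in (bases, revcomp(bases)):
        full = edlib.align(seq, reference, mode="HW", task="distance", k=max_full)[
            "editDistance"
        ]
        if full < min_margin:  # well explained without a jump
            continue
        L, M = len(seq), len(reference)
        F = _semiglobal_dp(seq, reference)
        B = _semiglobal_dp(seq[::-1], reference[::-1])[::-1, ::-1]
        # B[q][t] = cost of aligning read[q:] starting at reference pos t
        pref = np.minimum.accumulate(F, axis=1)
        totals = B[:, min_del:] + pref[:, : M + 1 - min_del]
        block = totals[anchor : L - anchor + 1]
        q_off, k = np.unravel_index(int(np.argmin(block)), block.shape)
        cost = int(block[q_off, k])
        if cost > max_split_cost or full - cost < min_margin:
            continue
        q = anchor + int(q_off)
        t2 = int(k) + min_del
        t1 = int(np.argmin(F[q][: t2 - min_del + 1]))
        net = (t2 - t1) % period
        if net < min_del or net > period - min_del:
            continue
        if best is None or cost < best[0]:
            best = (cost, t1, t2)
    if best is None:
        return None
    _, t1, t2 = best
    return t1 % period, (t2 - t1) % period


def detect_monomer_variants(
    profile: SatelliteProfile,
    family_reads: list[ReadRecord],
    min_support: int = 5,
    anchor: int = 15,
    min_del: int = 10,
    position_tolerance: int = 5,
    max_split_cost: int = 8,
    min_margin: int = 6,
) -> list[MonomerVariant]:
    """Find consistently deleted monomer forms among a family's reads.

    Each read is aligned to the tandem consensus with one free jump
    allowed (spliced alignment; see ``_split_deletion``); jumps that recur
    at the same monomer position and net length across at least
    ``min_support`` reads define a variant. Two fractions are reported:

    * ``read_fraction`` — deletion-supporting reads as a percentage of the
      family's reads (the raw observable);
    * ``family_fraction`` — the estimated percentage of monomer *copies*
      that carry the variant. A read only reveals the deletion when it
      spans the deletion junction with ``anchor`` bases on both sides, a
      window of (read length - 2 x anchor) per variant copy, so the raw
      read fraction understates the copy fraction by about window/period.
      ``family_fraction`` rescales by period/window to undo this.
    """
    if not family_reads:
        raise ValueError("family_reads is empty")
    p = profile.period
    cons = profile.consensus_monomer
    read_len = max(len(r) for r in family_reads)
    n_units = math.ceil((read_len + 2 * p) / p) + 2
    reference = cons * n_units

    observations: list[tuple[int, int]] = []
    for r in family_reads:
        hit = _split_deletion(
            r.bases, reference, p, anchor, min_del, max_split_cost, min_margin
        )
        if hit is not None:
            observations.append(hit)

    groups: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for start, d_len in sorted(observations):
        placed = False
        for (g_start, g_len), members in groups.items():
            circ = min((start - g_start) % p, (g_start - start) % p)
            if circ <= position_tolerance and abs(d_len - g_len) <= 2:
                members.append((start, d_len))
                placed = True
                break
        if not placed:
            groups[(start, d_len)].append((start, d_len))

    n_reads = len(family_reads)
    mean_len = sum(len(r) for r in family_reads) / n_reads
    window = max(1.0, mean_len - 2 * anchor)
    variants = []
    for members in groups.values():
        if len(members) < min_support:
            continue
        starts = [s for s, _ in members]
        lens = [l for _, l in members]
        start = Counter(starts).most_common(1)[0][0]
        d_len = Counter(lens).most_common(1)[0][0]
        seg = (cons * 2)[start : start + d_len]
        read_fraction = 100.0 * len(members) / n_reads
        family_fraction = min(100.0, read_fraction * p / window)
        variants.append(
            MonomerVariant(
                length=p - d_len,
                deleted_start=start,
                deleted_segment=seg,
                n_support=len(members),
                read_fraction=read_fraction,
                family_fraction=family_fraction,
            )
        )
    variants.sort(key=lambda v: -v.n_support)
    profile.variants = variants
    return variants


def satellite_table(
    entries: dict[str, dict[str, tuple[float, int]]],
    locations: dict[str, str] | None = None,
):
    """Ranked per-species satellite summary.

    ``entries`` maps species code -> {satellite name: (GP %, monomer bp)}.
    Satellites are ranked by GP within each species; a species lacking a
    satellite shows an em dash in its rank and GP columns.
    """
    import pandas as pd

    locations = locations or {}
    names: list[str] = []
    for per_species in entries.values():
        for name in per_species:
            if name not in names:
                names.append(name)
    names.sort(key=lambda n: -max(sp.get(n, (0.0, 0))[0] for sp in entries.values()))

    rows = []
    ranks: dict[str, dict[str, int]] = {}
    for code, per_species in entries.items():
        ordered = sorted(per_species.items(), key=lambda kv: -kv[1][0])
        ranks[code] = {name: i + 1 for i, (name, _) in enumerate(ordered)}
    for name in names:
        row: dict[str, object] = {"satellite": name}
        length = None
        for code, per_species in entries.items():
            if name in per_species:
                gp, mono_len = per_species[name]
                row[f"{code}_rank"] = ranks[code][name]
                row[f"{code}_gp"] = round(gp, 2)
                length = mono_len if length is None else length
            else:
                row[f"{code}_rank"] = "—"
                row[f"{code}_gp"] = "—"
        row["length_bp"] = length
        row["location"] = locations.get(name, "")
        rows.append(row)
    return pd.DataFrame(rows)
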