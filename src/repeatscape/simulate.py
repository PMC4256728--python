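"""Synthetic genomes and read sets with known repeat structure.

The generator builds genomes the way the analysis assumes real ones look:
dispersed LTR-like families at controlled genome proportions, tandem
satellite arrays with an optional shorter deletion-variant monomer, an
rDNA-like component, and single-copy background. It then samples paired-end
reads (optionally CenH3-ChIP-enriched for one family) with per-read truth
labels, so every downstream stage can be scored against ground truth.

Placement is exact bookkeeping, not sampling: each family's realized genome
proportion is recorded in the truth table. Copies of dispersed families are
mutated by independent substitutions only; background is i.i.d. uniform DNA
so that single-copy sequence cannot form clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._dna import mutate, random_dna, revcomp
from .io import ReadPair, ReadRecord

FAMILY_KINDS = ("LTR_copia", "LTR_gypsy", "DNA_transposon", "satellite", "rDNA")
BACKGROUND = "background"


@dataclass
class RepeatFamilySpec:
    """One repeat family to plant in a synthetic genome.

    ``target_gp`` is the fraction of the genome the family should occupy.
    For satellites, copies are monomers laid head-to-tail in arrays;
    ``variant_fraction`` of the monomer copies carry a fixed internal
    deletion that shortens them to ``variant_monomer_length``.
    """

    family_id: str
    kind: str
    template_length: int
    target_gp: float
    monomer_length: int | None = None
    variant_monomer_length: int | None = None
    variant_fraction: float = 0.0
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in FAMILY_KINDS:
            raise ValueError(f"unknown family kind {self.kind!r}")
        if not (0.0 <= self.target_gp < 1.0):
            raise ValueError("target_gp must be in [0, 1)")
        if self.kind == "satellite":
            if self.monomer_length is None:
                self.monomer_length = self.template_length
            if self.monomer_length <= 0:
                raise ValueError("satellite monomer_length must be positive")
        if self.variant_monomer_length is None and self.variant_fraction != 0.0:
            raise ValueError("variant_fraction must be 0 when no variant is given")
        if self.variant_monomer_length is not None:
            if self.kind != "satellite":
                raise ValueError("variant monomers only apply to satellites")
            if not (0 < self.variant_monomer_length < self.monomer_length):
                raise ValueError("variant monomer must be shorter than the monomer")


@dataclass
class GenomeSpec:
    """A synthetic species genome: size, families, and a simulation seed."""

    species_code: str
    genome_size: int
    families: list[RepeatFamilySpec] = field(default_factory=list)
    shared_with: Mapping[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        gp_sum = sum(f.target_gp for f in self.families)
        if gp_sum >= 1.0:
            raise ValueError(f"family target_gp values sum to {gp_sum:.3f} >= 1")
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family_id in GenomeSpec")


@dataclass
class ReadSimSpec:
    """Paired-end read simulation parameters (100 bp Illumina-like)."""

    n_pairs: int
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    error_rate: float = 0.0
    chip_target_family: str | None = None
    chip_enrichment_fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.chip_enrichment_fold < 1.0:
            raise ValueError("chip_enrichment_fold must be >= 1")


@dataclass
class SimulatedGenome:
    """A generated genome plus its truth table.

    The truth table has one row per planted copy (per monomer copy for
    satellites) with 0-based half-open coordinates:
    ``family_id, start, end, copy_index, is_variant``.
    """

    species_code: str
    sequence: str
    truth: pd.DataFrame
    realized_gp: dict[str, float]
    families: dict[str, RepeatFamilySpec]
    templates: dict[str, str]

    def family_intervals(self, family_id: str) -> list[tuple[int, int]]:
        sub = self.truth[self.truth.family_id == family_id]
        return list(zip(sub.start.tolist(), sub.end.tolist()))


def _family_fragments(
    rng: np.random.Generator, fam: RepeatFamilySpec, total_bp: int, template: str
) -> list[tuple[str, list[tuple[str, int, bool]]]]:
    """Build the sequence blocks for one family.

    Returns a list of (block_sequence, copies) where copies are
    (family_id, copy_length, is_variant) in block order. Dispersed families
    yield one block per copy; satellites yield a few multi-monomer arrays.
    """
    if fam.kind == "satellite":
        mono = fam.monomer_length
        n_copies = max(2, round(total_bp / mono))
        # split into 1-3 arrays of at least 2 monomers each
        n_arrays = min(3, max(1, n_copies // 20))
        sizes = [n_copies // n_arrays] * n_arrays
        sizes[0] += n_copies - sum(sizes)
        del_len = (
            mono - fam.variant_monomer_length if fam.variant_monomer_length else 0
        )
        # the deleted segment is fixed per family: one internal interval
        del_start = int(rng.integers(1, mono - del_len)) if del_len else 0
        variant = (
            template[:del_start] + template[del_start + del_len :] if del_len else None
        )
        blocks = []
        for size in sizes:
            parts, copies = [], []
            for _ in range(size):
                is_var = bool(variant) and rng.random() < fam.variant_fraction
                src = variant if is_var else template
                copy = mutate(rng, src, fam.divergence)
                parts.append(copy)
                copies.append((fam.family_id, len(copy), is_var))
            blocks.append(("".join(parts), copies))
        return blocks
    n_copies = max(1, round(total_bp / fam.template_length))
    blocks = []
    for _ in range(n_copies):
        copy = mutate(rng, template, fam.divergence)
        blocks.append((copy, [(fam.family_id, len(copy), False)]))
    return blocks


def simulate_genome(
    spec: GenomeSpec,
    templates: Mapping[str, str] | None = None,
    min_gap: int = 200,
) -> SimulatedGenome:
    """Generate a genome sequence and its truth table from a GenomeSpec.

    ``templates`` optionally supplies the master sequence per family
    (used to plant the same family in several species); missing templates
    are drawn at random from the spec's seed. ``min_gap`` is the minimum
    background spacer between planted blocks (dispersed copies really are
    dispersed; without a floor, two blocks can land nearly adjacent and
    read chains across the sliver of background would fuse unrelated
    families during clustering). It shrinks automatically when background
    is scarce.
    """
    rng = np.random.default_rng(spec.seed)
    templates = dict(templates or {})
    for fam in spec.families:
        if fam.family_id not in templates:
            length = (
                fam.monomer_length if fam.kind == "satellite" else fam.template_length
            )
            templates[fam.family_id] = random_dna(rng, length)

    all_blocks: list[tuple[str, list[tuple[str, int, bool]]]] = []
    for fam in spec.families:
        total_bp = int(round(fam.target_gp * spec.genome_size))
        all_blocks.extend(
            _family_fragments(rng, fam, total_bp, templates[fam.family_id])
        )

    repeat_bp = sum(len(seq) for seq, _ in all_blocks)
    background_bp = spec.genome_size - repeat_bp
    if background_bp < 0:
        raise ValueError(
            f"infeasible packing: families need {repeat_bp} bp but genome_size "
            f"is {spec.genome_size} bp"
        )

    order = rng.permutation(len(all_blocks))
    # split background into len(blocks)+1 chunks: a fixed spacer floor per
    # gap plus a random split of the remainder
    n_gaps = len(all_blocks) + 1
    if background_bp > 0 and n_gaps > 1:
        base = min(min_gap, background_bp // n_gaps)
        spare = background_bp - base * n_gaps
        cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
        gap_sizes = base + np.diff(np.concatenate([[0], cuts, [spare]]))
    else:
        gap_sizes = np.array([background_bp] + [0] * (n_gaps - 1))

    parts: list[str] = []
    rows: list[tuple[str, int, int, int, bool]] = []
    pos = 0
    copy_counter: dict[str, int] = {}
    for slot, block_i in enumerate(order):
        gap = int(gap_sizes[slot])
        if gap:
            parts.append(random_dna(rng, gap))
            pos += gap
        seq, copies = all_blocks[block_i]
        offset = pos
        for fam_id, length, is_var in copies:
            idx = copy_counter.get(fam_id, 0)
            copy_counter[fam_id] = idx + 1
            rows.append((fam_id, offset, offset + length, idx, is_var))
            offset += length
        parts.append(seq)
        pos += len(seq)
    tail = int(gap_sizes[len(all_blocks)])
    if tail:
        parts.append(random_dna(rng, tail))
        pos += tail

    sequence = "".join(parts)
    truth = pd.DataFrame(
        rows, columns=["family_id", "start", "end", "copy_index", "is_variant"]
    ).sort_values("start", ignore_index=True)
    realized = {
        fam.family_id: float(
            (truth.end - truth.start)[truth.family_id == fam.family_id].sum()
        )
        / spec.genome_size
        for fam in spec.families
    }
    return SimulatedGenome(
        species_code=spec.species_code,
        sequence=sequence,
        truth=truth,
        realized_gp=realized,
        families={f.family_id: f for f in spec.families},
        templates=templates,
    )


def _truth_labeler(genome: SimulatedGenome):
    """Return a function labeling [start, end) read intervals by majority overlap.

    A read is labeled with a family if >= 50% of its bases fall inside that
    family's planted coordinates; otherwise it is background.
    """
    truth = genome.truth
    starts = truth.start.to_numpy()
    ends = truth.end.to_numpy()
    fams = truth.family_id.to_numpy()

    def label(s: int, e: int) -> str:
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        best_fam, overlap_by_fam = BACKGROUND, {}
        for i in range(lo, hi):
            ov = min(e, ends[i]) - max(s, starts[i])
            if ov > 0:
                overlap_by_fam[fams[i]] = overlap_by_fam.get(fams[i], 0) + ov
        if overlap_by_fam:
            fam, ov = max(overlap_by_fam.items(), key=lambda kv: kv[1])
            if ov >= 0.5 * (e - s):
                best_fam = fam
        return best_fam

    return label


def _sample_pair(
    rng: np.random.Generator,
    sequence: str,
    spec: ReadSimSpec,
    start: int | None = None,
) -> tuple[int, int, bool, str, str]:
    """Sample one fragment; returns (start, end, minus_strand, read1, read2)."""
    glen = len(sequence)
    insert = int(np.clip(round(rng.normal(spec.insert_mean, spec.insert_sd)),
                         spec.read_length, glen))
    if start is None:
        start = int(rng.integers(0, glen - insert + 1))
    else:
        start = min(start, glen - insert)
    frag = sequence[start : start + insert]
    minus = bool(rng.random() < 0.5)
    if minus:
        frag = revcomp(frag)
    r1 = frag[: spec.read_length]
    r2 = revcomp(frag[-spec.read_length :])
    if spec.error_rate > 0:
        r1 = mutate(rng, r1, spec.error_rate)
        r2 = mutate(rng, r2, spec.error_rate)
    return start, start + insert, minus, r1, r2


def simulate_reads(
    genome: SimulatedGenome, spec: ReadSimSpec
) -> tuple[list[ReadPair], dict[str, str]]:
    """Sample paired-end reads uniformly from both strands of the genome.

    Returns (pairs, truth_labels) where truth_labels maps each read id to
    its source family or ``"background"``. Deterministic under the spec's
    seed; fixed seed gives byte-identical FASTQ downstream.
    """
    if len(genome.sequence) == 0:
        raise ValueError("genome sequence is empty")
    if spec.read_length > len(genome.sequence):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(spec.seed)
    label = _truth_labeler(genome)
    pairs: list[ReadPair] = []
    labels: dict[str, str] = {}
    code = genome.species_code
    for i in range(spec.n_pairs):
        s, e, minus, b1, b2 = _sample_pair(rng, genome.sequence, spec)
        rid = f"{code}_r{i:07d}"
        L = spec.read_length
        if minus:
            span1, span2 = (e - L, e), (s, s + L)
        else:
            span1, span2 = (s, s + L), (e - L, e)
        r1 = ReadRecord(rid + "/1", b1)
        r2 = ReadRecord(rid + "/2", b2)
        labels[r1.read_id] = label(*span1)
        labels[r2.read_id] = label(*span2)
        pairs.append((r1, r2))
    return pairs, labels


def simulate_chip_reads(
    genome: SimulatedGenome, spec: ReadSimSpec
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Simulate a ChIP read set plus a matched uniform input (mock) set.

    In the ChIP set the per-base sampling density over the target family's
    copies is ``chip_enrichment_fold`` times the background density; the
    input set is sampled uniformly. Both sets have ``n_pairs`` pairs.
    """
    fam_id = spec.chip_target_family
    if fam_id is None or fam_id not in genome.families:
        raise ValueError("chip_target_family must name a family in the genome")
    rng = np.random.default_rng(spec.seed)
    intervals = genome.family_intervals(fam_id)
    fam_bp = sum(e - s for s, e in intervals)
    glen = len(genome.sequence)
    bg_bp = glen - fam_bp
    fold = spec.chip_enrichment_fold
    p_family = fold * fam_bp / (fold * fam_bp + bg_bp)

    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    lengths = (ends - starts).astype(float)
    cum = np.cumsum(lengths) / lengths.sum()
    # background coordinates = genome minus the target family's intervals,
    # so the two sampling branches partition the genome exactly
    bg_starts = np.concatenate([[0], ends])
    bg_ends = np.concatenate([starts, [glen]])
    bg_lens = (bg_ends - bg_starts).clip(min=0)
    bg_cum = np.cumsum(bg_lens)

    chip: list[ReadPair] = []
    code = genome.species_code
    for i in range(spec.n_pairs):
        if rng.random() < p_family:
            # uniform position within the target family's planted bases
            j = int(np.searchsorted(cum, rng.random(), side="right"))
            j = min(j, len(starts) - 1)
            pos = int(starts[j] + rng.integers(0, max(1, int(lengths[j]))))
        else:
            # uniform position within background (non-family) bases
            u = int(rng.integers(0, bg_bp))
            j = int(np.searchsorted(bg_cum, u, side="right"))
            pos = int(bg_starts[j] + (u - (bg_cum[j] - bg_lens[j])))
        s, e, minus, b1, b2 = _sample_pair(rng, genome.sequence, spec, start=pos)
        rid = f"{code}_chip{i:07d}"
        chip.append((ReadRecord(rid + "/1", b1), ReadRecord(rid + "/2", b2)))

    input_spec = ReadSimSpec(
        n_pairs=spec.n_pairs,
        read_length=spec.read_length,
        insert_mean=spec.insert_mean,
        insert_sd=spec.insert_sd,
        error_rate=spec.error_rate,
        seed=spec.seed + 1,
    )
    input_pairs, _ = simulate_reads(genome, input_spec)
    renamed: list[ReadPair] = []
    for i, (r1, r2) in enumerate(input_pairs):
        rid = f"{code}_input{i:07d}"
        renamed.append(
            (ReadRecord(rid + "/1", r1.bases), ReadRecord(rid + "/2", r2.bases))
        )
    return chip, renamed
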