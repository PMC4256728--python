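"""Read records, FASTQ I/O, read preprocessing and dataset assembly.

Reads are the currency of the whole pipeline: repeat families are inferred
directly from unassembled low-coverage reads, so careful pairing and
bookkeeping here (synchronised mates, species codes on combined datasets)
is what keeps every downstream proportion interpretable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import round_half_up

SPECIES_SEP = "|"


@dataclass
class ReadRecord:
    """A single sequenced read.

    ``species_code`` is set only on reads that belong to a combined
    multi-species dataset, where it acts as the sample code carried in the
    read id (``CODE|readid``).
    """

    read_id: str
    bases: str
    qualities: list[int] = field(default_factory=list)
    species_code: str | None = None

    def __post_init__(self) -> None:
        if not self.qualities:
            self.qualities = [40] * len(self.bases)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0

    @property
    def n_fraction(self) -> float:
        if not self.bases:
            return 0.0
        return self.bases.upper().count("N") / len(self.bases)

    def pair_key(self) -> str:
        """Template id shared by both mates (strips a /1, /2 suffix)."""
        rid = self.read_id
        if len(rid) > 2 and rid[-2] == "/" and rid[-1] in "12":
            return rid[:-2]
        return rid


ReadPair = tuple[ReadRecord, ReadRecord]


@dataclass(frozen=True)
class SequencingStats:
    """Per-species sequencing throughput summary.

    ``coverage`` follows the convention total read length / (2 x genome
    size): the factor 2 reflects that both mates of a pair derive from the
    same template, so pair coverage of unique sequence is half the raw base
    count. Display values are rounded half-up to 2 decimals.
    """

    n_reads: int
    read_length: int
    total_read_length_mb: float
    genome_size_mb: float
    coverage: float


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a (possibly gzipped) FASTQ file.

    A ``CODE|`` prefix on the read id is interpreted as a species code.
    """
    with _open(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            rid = rec.id
            species = None
            if SPECIES_SEP in rid:
                species, rid = rid.split(SPECIES_SEP, 1)
            yield ReadRecord(
                read_id=rid,
                bases=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                species_code=species,
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as Sanger FASTQ (Phred+33); returns the record count."""
    n = 0
    with _open(path, "wt") as handle:
        for r in records:
            rid = r.read_id
            if r.species_code is not None:
                rid = f"{r.species_code}{SPECIES_SEP}{rid}"
            rec = SeqRecord(Seq(r.bases), id=rid, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Iterate synchronized mate pairs from two FASTQ files."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for r1 in it1:
        try:
            r2 = next(it2)
        except StopIteration:
            raise ValueError(f"mate file exhausted; unpaired read {r1.read_id}")
        if r1.pair_key() != r2.pair_key():
            raise ValueError(
                f"desynchronized mate files at read {r1.read_id!r} / {r2.read_id!r}"
            )
        yield (r1, r2)
    try:
        extra = next(it2)
    except StopIteration:
        return
    raise ValueError(f"mate file exhausted; unpaired read {extra.read_id}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id_with_description, sequence) tuples from a FASTA file."""
    out = []
    with _open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.description if rec.description else rec.id
            out.append((name, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    n = 0
    with _open(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
            n += 1
    return n


def preprocess_reads(
    pairs: Iterable[ReadPair],
    min_mean_quality: float = 20.0,
    max_n_fraction: float = 0.10,
) -> tuple[list[ReadPair], int]:
    """Quality-filter mate pairs, discarding whole pairs.

    A read fails if its mean Phred score is below ``min_mean_quality`` or
    more than ``max_n_fraction`` of its bases are N. If either mate fails,
    both are discarded so the output contains no orphans.

    Returns (kept pairs, number of discarded pairs).
    """

    def ok(r: ReadRecord) -> bool:
        return r.mean_quality >= min_mean_quality and r.n_fraction <= max_n_fraction

    kept: list[ReadPair] = []
    discarded = 0
    for r1, r2 in pairs:
        if r1.pair_key() != r2.pair_key():
            raise ValueError(f"desynchronized mates: {r1.read_id!r} vs {r2.read_id!r}")
        if ok(r1) and ok(r2):
            kept.append((r1, r2))
        else:
            discarded += 1
    return kept, discarded


def subsample_combined(
    datasets: Sequence[tuple[str, Sequence[ReadRecord]]],
    n_total: int,
    seed: int = 0,
    quotas: dict[str, int] | None = None,
) -> list[ReadRecord]:
    """Build a combined multi-species dataset of exactly ``n_total`` reads.

    Each species contributes its quota (default: equal split, remainder to
    the earliest-listed species), sampled without replacement. Every output
    record carries its species code. Deterministic under ``seed``.
    """
    if n_total < 0:
        raise ValueError("n_total must be nonnegative")
    codes = [code for code, _ in datasets]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate species codes in datasets")
    if quotas is None:
        k = len(datasets)
        base, rem = divmod(n_total, k)
        quotas = {code: base + (1 if i < rem else 0) for i, code in enumerate(codes)}
    if sum(quotas.values()) != n_total:
        raise ValueError("quotas do not sum to n_total")

    rng = np.random.default_rng(seed)
    combined: list[ReadRecord] = []
    for code, records in datasets:
        records = list(records)
        q = quotas.get(code, 0)
        if q > len(records):
            raise ValueError(
                f"species {code}: quota {q} exceeds available {len(records)} reads"
            )
        idx = rng.choice(len(records), size=q, replace=False)
        for i in sorted(idx):
            r = records[i]
            combined.append(
                ReadRecord(r.read_id, r.bases, list(r.qualities), species_code=code)
            )
    return combined


def compute_sequencing_stats(
    n_reads: int, read_length: int, genome_size_mb: float
) -> SequencingStats:
    """Throughput and fold-coverage from read count, read length and 1C size."""
    if n_reads <= 0 or read_length <= 0 or genome_size_mb <= 0:
        raise ValueError("n_reads, read_length and genome_size_mb must be positive")
    total_mb = n_reads * read_length / 1e6
    coverage = total_mb / (2.0 * genome_size_mb)
    return SequencingStats(
        n_reads=n_reads,
        read_length=read_length,
        total_read_length_mb=round_half_up(total_mb, 2),
        genome_size_mb=genome_size_mb,
        coverage=round_half_up(coverage, 2),
    )
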