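"""End-to-end orchestration: FASTQ in, report tables out.

Stages run in a fixed order (preprocess -> cluster -> annotate ->
satellite -> comparative -> chip -> phylo), each writing plain TSV/FASTA
outputs into the run directory so any stage can be re-run or inspected in
isolation. A manifest records package version, seed, thresholds and input
checksums; deterministic stages are bit-identical under an unchanged
config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    AnnotationConfig,
    annotate_cluster,
    eliminate_organelle_clusters,
    parse_library,
    summarize_superfamilies,
)
from .chip import ChipMapConfig, compute_enrichment, map_reads_to_clusters
from .clustering import (
    ClusteringConfig,
    Contig,
    RepeatCluster,
    assemble_cluster_contigs,
    build_similarity_graph,
    partition_graph,
    total_repeat_fraction,
)
from .comparative import comparative_cluster_analysis, pattern_summary
from .io import (
    ReadRecord,
    preprocess_reads,
    read_fasta,
    read_fastq_pairs,
    write_fasta,
)
from .phylogeny import (
    bootstrap_support,
    pairwise_distances,
    progressive_align,
    select_rt_representative,
)
from .satellite import detect_monomer_variants, profile_cluster


@dataclass
class SpeciesInput:
    code: str
    fastq1: str
    fastq2: str


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with a single global seed."""

    outdir: str
    species: list[SpeciesInput] = field(default_factory=list)
    seed: int = 0
    min_mean_quality: float = 20.0
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    chip_map: ChipMapConfig = field(default_factory=ChipMapConfig)
    repeat_library: str | None = None
    organelle_library: str | None = None
    rt_references: str | None = None
    chip_fastq: tuple[str, str] | None = None
    input_fastq: tuple[str, str] | None = None
    negative_controls: list[str] = field(default_factory=list)
    bootstrap_replicates: int = 100

    def validate(self) -> None:
        paths = [(s.fastq1, f"species {s.code} fastq1") for s in self.species]
        paths += [(s.fastq2, f"species {s.code} fastq2") for s in self.species]
        for attr in ("repeat_library", "organelle_library", "rt_references"):
            p = getattr(self, attr)
            if p:
                paths.append((p, attr))
        for pair_attr in ("chip_fastq", "input_fastq"):
            pair = getattr(self, pair_attr)
            if pair:
                paths += [(pair[0], pair_attr), (pair[1], pair_attr)]
        for p, label in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {label}: missing path {p}")


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    """Plain TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        cols = (["index"] if index else []) + list(df.columns)
        fh.write("#" + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index)


def save_clusters(clusters: list[RepeatCluster], outdir: Path) -> None:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "n_reads": c.n_reads,
            "genome_proportion": round(c.genome_proportion, 6),
            "detailed": int(c.detailed),
            "annotation": c.annotation or "",
        }
        for c in clusters
    ]
    write_tsv(pd.DataFrame(rows), outdir / "clusters.tsv")
    members = [
        {"read_id": rid, "cluster_id": c.cluster_id}
        for c in clusters
        for rid in c.read_ids
    ]
    write_tsv(pd.DataFrame(members), outdir / "cluster_members.tsv")
    contigs = [
        (f"{contig.contig_id} reads={contig.n_reads}", contig.sequence)
        for c in clusters
        if c.detailed
        for contig in c.contigs
    ]
    if contigs:
        write_fasta(contigs, outdir / "contigs.fasta")


def load_clusters(outdir: Path) -> list[RepeatCluster]:
    info = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    info.columns = [c.lstrip("#") for c in info.columns]
    members = pd.read_csv(outdir / "cluster_members.tsv", sep="\t")
    members.columns = [c.lstrip("#") for c in members.columns]
    by_cluster = members.groupby("cluster_id").read_id.apply(list).to_dict()
    contigs_by_cluster: dict[str, list[Contig]] = {}
    contig_path = outdir / "contigs.fasta"
    if contig_path.exists():
        for name, seq in read_fasta(contig_path):
            cid = name.split()[0]
            owner = cid.split("c")[0]
            n_reads = int(name.split("reads=")[1]) if "reads=" in name else 0
            contigs_by_cluster.setdefault(owner, []).append(Contig(cid, seq, n_reads))
    clusters = []
    for row in info.itertuples():
        ann = row.annotation if isinstance(row.annotation, str) and row.annotation else None
        clusters.append(
            RepeatCluster(
                cluster_id=row.cluster_id,
                read_ids=sorted(by_cluster.get(row.cluster_id, [])),
                n_reads=int(row.n_reads),
                genome_proportion=float(row.genome_proportion),
                detailed=bool(row.detailed),
                contigs=contigs_by_cluster.get(row.cluster_id, []),
                annotation=ann,
            )
        )
    return clusters


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the output directory.

    A stage failure raises with the stage name and cause so partial runs
    are diagnosable from the log alone.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "repeatscape",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "clustering": asdict(config.clustering),
            "annotation": asdict(config.annotation),
            "chip_map": asdict(config.chip_map),
            "min_mean_quality": config.min_mean_quality,
        },
        "inputs": {},
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        return name

    try:
        stage("preprocess")
        reads: list[ReadRecord] = []
        discard_rows = []
        for sp in config.species:
            pairs = list(read_fastq_pairs(sp.fastq1, sp.fastq2))
            kept, discarded = preprocess_reads(pairs, config.min_mean_quality)
            discard_rows.append(
                {"species": sp.code, "pairs_in": len(pairs),
                 "pairs_kept": len(kept), "pairs_discarded": discarded}
            )
            for r1, r2 in kept:
                if len(config.species) > 1:
                    r1.species_code = sp.code
                    r2.species_code = sp.code
                reads.extend((r1, r2))
            manifest["inputs"][sp.code] = {
                "fastq1": _checksum(sp.fastq1),
                "fastq2": _checksum(sp.fastq2),
            }
        write_tsv(pd.DataFrame(discard_rows), outdir / "preprocess.tsv")
        if not reads:
            raise ValueError("no reads survived preprocessing")

        stage("cluster")
        reads_by_id = {
            (f"{r.species_code}|{r.read_id}" if r.species_code else r.read_id): r
            for r in reads
        }
        keyed_reads = [
            ReadRecord(rid, r.bases, list(r.qualities), r.species_code)
            for rid, r in reads_by_id.items()
        ]
        edges = build_similarity_graph(keyed_reads, config.clustering)
        clusters = partition_graph(edges, keyed_reads, config.clustering)
        for c in clusters:
            if c.detailed:
                c.contigs = assemble_cluster_contigs(c, reads_by_id, edges)

        if config.repeat_library or config.organelle_library:
            stage("annotate")
            if config.organelle_library:
                organelle = parse_library(read_fasta(config.organelle_library))
                clusters, removed = eliminate_organelle_clusters(
                    clusters, organelle, config.annotation
                )
                write_tsv(
                    pd.DataFrame(
                        [{"cluster_id": c.cluster_id, "n_reads": c.n_reads}
                         for c in removed]
                    ),
                    outdir / "organelle_removed.tsv",
                )
            if config.repeat_library:
                library = parse_library(read_fasta(config.repeat_library))
                for c in clusters:
                    if c.detailed:
                        annotate_cluster(c, library, config.annotation)
                write_tsv(
                    summarize_superfamilies(clusters).reset_index(names="superfamily"),
                    outdir / "superfamily_summary.tsv",
                )
        save_clusters(clusters, outdir)
        manifest["total_repeat_fraction_pct"] = round(
            total_repeat_fraction(clusters), 4
        )

        stage("satellite")
        profile_rows, variant_rows, consensus_fa = [], [], []
        for c in clusters:
            if not c.detailed:
                continue
            profile = profile_cluster(c)
            if profile is None:
                continue
            family_reads = [reads_by_id[rid] for rid in c.read_ids]
            variants = detect_monomer_variants(profile, family_reads)
            profile_rows.append(
                {"cluster_id": c.cluster_id, "period": profile.period,
                 "array_span": profile.array_span,
                 "genome_proportion": round(c.genome_proportion, 4)}
            )
            consensus_fa.append(
                (f"{c.cluster_id}_monomer period={profile.period}",
                 profile.consensus_monomer)
            )
            for v in variants:
                variant_rows.append(
                    {"cluster_id": c.cluster_id, "variant_length": v.length,
                     "n_support": v.n_support,
                     "family_fraction_pct": round(v.family_fraction, 3),
                     "read_fraction_pct": round(v.read_fraction, 3),
                     "deleted_segment": v.deleted_segment}
                )
        write_tsv(pd.DataFrame(profile_rows), outdir / "satellites.tsv")
        write_tsv(pd.DataFrame(variant_rows), outdir / "satellite_variants.tsv")
        if consensus_fa:
            write_fasta(consensus_fa, outdir / "satellite_monomers.fasta")

        codes = {r.species_code for r in reads if r.species_code}
        if len(codes) >= 2:
            stage("comparative")
            table = comparative_cluster_analysis(keyed_reads, clusters=clusters)
            write_tsv(table, outdir / "comparative.tsv")
            if not table.empty:
                write_tsv(pattern_summary(table), outdir / "patterns.tsv")

        if config.chip_fastq and config.input_fastq:
            stage("chip")
            detailed = [c for c in clusters if c.detailed]
            chip_reads = [
                r
                for pair in read_fastq_pairs(*config.chip_fastq)
                for r in pair
            ]
            input_reads = [
                r
                for pair in read_fastq_pairs(*config.input_fastq)
                for r in pair
            ]
            a_chip = map_reads_to_clusters(
                chip_reads, detailed, reads_by_id, config.chip_map
            )
            a_input = map_reads_to_clusters(
                input_reads, detailed, reads_by_id, config.chip_map
            )
            write_tsv(
                pd.DataFrame(
                    [{"read_id": rid, "cluster_id": cid, "distance": d}
                     for rid, (cid, d) in sorted(a_chip.items())]
                ),
                outdir / "chip_assignments.tsv",
            )
            negatives = config.negative_controls or [
                c.cluster_id
                for c in detailed
                if c.annotation in ("rDNA", "Satellite")
            ]
            results = compute_enrichment(
                a_chip, a_input, len(chip_reads), len(input_reads),
                detailed, negatives,
            )
            write_tsv(
                pd.DataFrame(
                    [{"cluster_id": r.cluster_id,
                      "chip_fraction": round(r.chip_fraction, 6),
                      "input_fraction": round(r.input_fraction, 6),
                      "fold": "" if r.fold is None else round(r.fold, 4),
                      "normalized_fold": ""
                      if r.normalized_fold is None
                      else round(r.normalized_fold, 4),
                      "se": "" if r.se is None else round(r.se, 4)}
                     for r in results.values()]
                ),
                outdir / "chip_enrichment.tsv",
            )

        if config.rt_references:
            stage("phylo")
            refs = [
                (name.split()[0], seq)
                for name, seq in read_fasta(config.rt_references)
            ]
            family_contigs = {
                c.cluster_id: c.contigs for c in clusters if c.detailed and c.contigs
            }
            reps, dropped = select_rt_representative(family_contigs, refs)
            manifest["phylo_dropped_families"] = dropped
            peptides = [(fid, rep.rt_peptide) for fid, rep in sorted(reps.items())]
            peptides += refs
            if len(peptides) >= 3:
                aligned = progressive_align(peptides)
                dm = pairwise_distances(aligned)
                tree = bootstrap_support(
                    aligned, config.bootstrap_replicates, seed=config.seed
                )
                with open(outdir / "rt_tree.nwk", "w") as fh:
                    fh.write(tree.newick(with_support=True) + "\n")
                with open(outdir / "rt_distances.phylip", "w") as fh:
                    fh.write(f"{len(dm.taxa)}\n")
                    for i, taxon in enumerate(dm.taxa):
                        row = " ".join(f"{x:.6f}" for x in dm.d[i])
                        fh.write(f"{taxon[:10]:<10} {row}\n")
                write_fasta(peptides, outdir / "rt_peptides.fasta")
    except Exception as err:
        current = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
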