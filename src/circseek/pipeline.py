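"""End-to-end orchestration: simulate → map → detect → annotate → diffexp
(→ sponge → clinstats), with a run manifest.

All randomness funnels through the single ``rng_seed`` in the config, so a
re-run with identical inputs and seed is byte-identical. The manifest
records parameters, per-stage output files with SHA-256 checksums, and row
counts, and is written as JSON next to the outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_candidates
from .core import ReferenceGenome
from .detect import detect_library, write_bed
from .diffexp import (build_count_matrix, differential_test, filter_de,
                      normalize_counts, write_results)
from .mapping import KmerIndex, ReadMapper, partition_reads
from .simulate import (SimConfig, generate_clinical_table, generate_genome,
                       plant_circrnas, simulate_reads, truth_table)
from .sponge import extract_circ_sequence, find_seed_matches, write_site_table
from .clinstats import clinical_report

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "circseek_out"
    sim: SimConfig = field(default_factory=SimConfig)
    anchor_len: int = 20
    max_mismatch: int = 2
    min_reads: int = 2
    unique_by: str = "sequence"
    fc: float = 2.0
    p: float = 0.05
    mirna_fasta: str | None = None
    clinical_csv: str | None = None
    covariates: tuple[str, ...] = ("sex", "t_stage")
    simulate_clinical: bool = True
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.rng_seed = self.rng_seed
        self.sim.anchor_len = self.anchor_len
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        # JSON round-trip turns tuples into YAML-safe lists
        data = json.loads(json.dumps(dataclasses.asdict(self)))
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "circseek", "version": __version__,
                      "parameters": {"anchor_len": config.anchor_len,
                                     "max_mismatch": config.max_mismatch,
                                     "min_reads": config.min_reads,
                                     "fc": config.fc, "p": config.p,
                                     "rng_seed": config.rng_seed},
                      "stages": {}, "files": {}}

    def register(name: str, path: Path, rows: int | None = None):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}
        if rows is not None:
            manifest["files"][name]["rows"] = rows

    # -- simulate ----------------------------------------------------------
    log.info("stage simulate")
    genome, annotation = generate_genome(config.sim)
    circs = plant_circrnas(genome, annotation, config.sim)
    fasta = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    truth_tsv = outdir / "circ_truth.tsv"
    genome.write_fasta(fasta)
    annotation.write_gtf(gtf)
    truth_table(circs).to_csv(truth_tsv, sep="\t", index=False)
    reads_dir = outdir / "reads"
    libraries, truth_counts = simulate_reads(genome, annotation, circs,
                                             config.sim, reads_dir)
    truth_counts.to_csv(outdir / "junction_truth_counts.tsv", sep="\t")
    register("genome", fasta)
    register("annotation", gtf, rows=annotation.n_exons())
    register("circ_truth", truth_tsv, rows=len(circs))
    manifest["stages"]["simulate"] = {
        "n_genes": len(annotation), "n_circs": len(circs),
        "n_libraries": len(libraries)}

    # -- map + detect per library -----------------------------------------
    log.info("stage map/detect")
    mapper = ReadMapper(genome, annotation, k=config.anchor_len,
                        max_mismatch=config.max_mismatch)
    anchor_index = (mapper.gindex if mapper.k == config.anchor_len
                    else KmerIndex.from_genome(genome, config.anchor_len))
    per_library: dict[str, dict[tuple, int]] = {}
    library_size: dict[str, int] = {}
    meta_rows = []
    for lib in libraries:
        mapped, unmapped, stats = partition_reads(
            lib.r1, lib.r2, mapper,
            unmapped_out=reads_dir / f"{lib.lib_id}_unmapped.fastq")
        candidates = detect_library(unmapped, genome, anchor_index,
                                    config.anchor_len, config.max_mismatch,
                                    config.min_reads, config.unique_by)
        per_library[lib.lib_id] = {c.key: c.junction_read_count
                                   for c in candidates}
        library_size[lib.lib_id] = stats["mapped"]
        meta_rows.append({"lib_id": lib.lib_id, "condition": lib.condition,
                          "pair_id": lib.pair_id})
    meta = pd.DataFrame(meta_rows).set_index("lib_id")
    manifest["stages"]["detect"] = {
        lib: len(d) for lib, d in per_library.items()}

    # -- aggregate, annotate, diffexp -------------------------------------
    log.info("stage annotate/diffexp")
    matrix = build_count_matrix(per_library, meta, library_size)
    pooled = detect_library(
        [r for lib in libraries for r in _read_unmapped(
            reads_dir / f"{lib.lib_id}_unmapped.fastq")],
        genome, anchor_index, config.anchor_len, config.max_mismatch,
        config.min_reads, config.unique_by)
    bed = outdir / "circ_candidates.bed"
    write_bed(pooled, bed)
    register("candidates_bed", bed, rows=len(pooled))
    assignments = annotate_candidates(pooled, annotation,
                                      outdir / "circ_annotated.tsv")
    register("annotated", outdir / "circ_annotated.tsv", rows=len(assignments))

    normalized = normalize_counts(matrix)
    results = differential_test(normalized, matrix, config.fc, config.p)
    up, down = filter_de(results)
    write_results(results, outdir / "diffexp.tsv")
    register("diffexp", outdir / "diffexp.tsv", rows=len(results))
    manifest["stages"]["diffexp"] = {"tested": len(results),
                                     "up": len(up), "down": len(down)}

    # -- sponge (optional) -------------------------------------------------
    if config.mirna_fasta:
        from Bio import SeqIO
        log.info("stage sponge")
        sites = []
        by_key = {a.circ_key: a for a in assignments}
        for rec in SeqIO.parse(config.mirna_fasta, "fasta"):
            for cand in pooled:
                mature = extract_circ_sequence(cand.key, genome, annotation,
                                               by_key.get(cand.key))
                sites.extend(find_seed_matches(mature, str(rec.seq), rec.id))
        write_site_table(sites, outdir / "sponge_sites.tsv")
        register("sponge_sites", outdir / "sponge_sites.tsv", rows=len(sites))
        manifest["stages"]["sponge"] = {"n_sites": len(sites)}

    # -- clinstats ---------------------------------------------------------
    if config.clinical_csv or config.simulate_clinical:
        log.info("stage clinstats")
        if config.clinical_csv:
            clinical = pd.read_csv(config.clinical_csv)
        else:
            clinical = generate_clinical_table(seed=config.rng_seed)
            clinical.to_csv(outdir / "clinical_synthetic.csv", index=False)
        covs = [c for c in config.covariates if c in clinical.columns]
        report = clinical_report(clinical, covs)
        report.to_csv(outdir / "clinstats.tsv", sep="\t", index=False)
        register("clinstats", outdir / "clinstats.tsv", rows=len(report))
        manifest["stages"]["clinstats"] = {
            "n_patients": len(clinical), "tests": len(report)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_unmapped(path: Path) -> list[tuple[str, str, str]]:
    from .mapping import iter_fastq

    out = []
    for read_id, seq in iter_fastq(path):
        base, _, mate = read_id.rpartition("/")
        out.append((base or read_id, mate or "1", seq))
    return out
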