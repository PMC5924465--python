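"""Pipeline orchestration: config, stages, manifests.

Each stage reads files, calls the library, and writes machine-readable
reports (TSV/JSON) plus a manifest recording the config hash, seed and
package version, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .annotate import annotate_genome, detect_reassignment
from .codes import get_code
from .elongate import coverage_stats, elongate_and_circularize, find_seed
from .io import (
    AnnotationSet,
    MitoGenome,
    read_fasta,
    read_fastq,
    read_genbank,
    write_fasta,
    write_genbank,
)
from .rearrange import (
    distance_matrix,
    gene_order_from_annotation,
    render_distance_table,
    restrict_to_shared,
    synteny_blocks,
)
from .simulate import GenomeSpec, generate_genome, simulate_reads
from .stats import (
    codon_usage,
    composition,
    find_perfect_repeats,
    nc_percent,
    size_nc_correlation,
    summarize_noncoding,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_annotate",
    "run_compare",
    "run_stats",
    "run_elongate",
    "run_simulate",
]


@dataclass
class PipelineConfig:
    """Thresholds and paths shared by the pipeline stages."""

    out_dir: str = "out"
    code_table: str = "mold"
    min_orf_len: int = 100
    min_urf_len: int = 100
    homology_floor: float = 0.3
    min_overlap: int = 25
    min_end_overlap: int = 25
    max_rounds: int = 200
    min_repeat_unit: int = 21
    filter_low_complexity: bool = True
    conservation_threshold: float = 0.7
    min_columns: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0, 1]")
        if self.min_overlap < 15:
            raise ValueError("min_overlap must be >= 15")
        if self.min_repeat_unit < 2:
            raise ValueError("min_repeat_unit must be >= 2")
        get_code(self.code_table)  # validates the name

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where outputs land does not change what they are
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, out: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
    }
    (out / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_refs(path: str | Path) -> dict[str, str]:
    """Labelled FASTA -> {label: sequence} (protein or nucleotide)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_annotate(
    cfg: PipelineConfig,
    fasta_in: str | Path,
    protein_refs: str | Path,
    rrna_refs: str | Path | None = None,
) -> list[Path]:
    """Annotate every genome in a FASTA file; write GenBank plus a URF report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = read_fasta(fasta_in)
    if not genomes:
        raise ValueError("no sequences")
    prefs = _load_refs(protein_refs)
    rrefs = _load_refs(rrna_refs) if rrna_refs else None
    code = get_code(cfg.code_table)
    written: list[Path] = []
    urf_rows = []
    for g in genomes:
        ann = annotate_genome(
            g, prefs, rrefs, code,
            min_orf_len=cfg.min_orf_len,
            min_urf_len=cfg.min_urf_len,
            homology_floor=cfg.homology_floor,
        )
        path = out / f"{g.id}.gb"
        write_genbank(g, ann, path)
        written.append(path)
        for f in ann:
            if f.kind == "URF":
                urf_rows.append(f"{g.id}\t{f.label}\t{f.start}\t{f.end}\t{f.length}")
    (out / "urf_report.tsv").write_text(
        "genome\tlabel\tstart\tend\tlength\n" + "".join(r + "\n" for r in urf_rows)
    )
    _write_manifest(cfg, out, "annotate")
    return written


def run_compare(cfg: PipelineConfig, genbank_paths: Sequence[str | Path]) -> Path:
    """Breakpoint-distance matrix and per-pair synteny blocks from >= 2 annotated genomes."""
    if len(genbank_paths) < 2:
        raise ValueError("need >= 2 annotated genomes")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    orders = []
    for p in genbank_paths:
        genome, ann = read_genbank(p)
        orders.append(gene_order_from_annotation(ann))
    mat = distance_matrix(orders)
    ids = list(mat.index)
    tsv_lines = ["a\tb\tbd\tn_shared\tbdn"]
    syn_lines = ["a\tb\tblock"]
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            res = mat.iloc[i, j]
            tsv_lines.append(f"{a}\t{b}\t{res.bd}\t{res.n_shared}\t{res.bdn_display:.2f}")
            ra, rb = restrict_to_shared(orders[i], orders[j])
            for blk in synteny_blocks(ra, rb):
                syn_lines.append(f"{a}\t{b}\t{'-'.join(blk.genes)}")
    (out / "breakpoints.tsv").write_text("\n".join(tsv_lines) + "\n")
    (out / "synteny_blocks.tsv").write_text("\n".join(syn_lines) + "\n")
    table = render_distance_table(mat)
    (out / "breakpoints_table.txt").write_text(table + "\n")
    _write_manifest(cfg, out, "compare")
    return out / "breakpoints.tsv"


def run_stats(cfg: PipelineConfig, genbank_paths: Sequence[str | Path]) -> Path:
    """Composition, codon usage, Table-2-shaped NC report, repeats, and the
    genome-size ~ NC-length correlation."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = get_code(cfg.code_table)
    nc_rows = []
    summary: dict = {"genomes": {}}
    corr_rows = []
    for p in genbank_paths:
        genome, ann = read_genbank(p)
        comp = composition(genome)
        usage = codon_usage(ann, genome, code)
        ncp = summarize_noncoding(ann, genome)
        reps = find_perfect_repeats(
            genome, cfg.min_repeat_unit, cfg.filter_low_complexity
        )
        nc_rows.append(
            "\t".join(
                str(x)
                for x in (
                    genome.id, ncp.genome_length, ncp.nc_with_urfs, ncp.nc_without_urfs,
                    ncp.n_nc_gt20_with, ncp.n_nc_gt20_without,
                    ncp.longest_nc_with[0], "-".join(ncp.longest_nc_with[1]),
                    ncp.longest_nc_without[0], "-".join(ncp.longest_nc_without[1]),
                )
            )
        )
        corr_rows.append((ncp.genome_length, ncp.nc_with_urfs))
        summary["genomes"][genome.id] = {
            "length": genome.length,
            "at_percent": round(comp.at_percent, 1),
            "nc_percent_with_urfs": nc_percent(ncp.nc_with_urfs, genome.length),
            "nc_percent_without_urfs": nc_percent(ncp.nc_without_urfs, genome.length),
            "total_codons": usage.total_codons,
            "longest_repeat_unit": max((r.unit_length for r in reps), default=0),
        }
        usage_lines = ["codon\tcount\tpercent"] + [
            f"{c}\t{usage.codon_counts[c]}\t{usage.percent(c):.2f}"
            for c in sorted(usage.codon_counts)
        ]
        (out / f"{genome.id}.codon_usage.tsv").write_text("\n".join(usage_lines) + "\n")
        rep_lines = ["start\tend\tunit_length\tpositions\tlow_complexity"] + [
            f"{r.positions[0]}\t{r.positions[0] + r.unit_length}\t{r.unit_length}\t"
            f"{','.join(map(str, r.positions))}\t{int(r.low_complexity)}"
            for r in reps
        ]
        (out / f"{genome.id}.repeats.tsv").write_text("\n".join(rep_lines) + "\n")
    header = (
        "genome\tgenome_length\tnc_with_urfs\tnc_without_urfs\t"
        "n_nc_gt20_with\tn_nc_gt20_without\tlongest_nc_with\tlocation_with\t"
        "longest_nc_without\tlocation_without"
    )
    (out / "noncoding.tsv").write_text(header + "\n" + "\n".join(nc_rows) + "\n")
    if len(corr_rows) >= 3:
        summary["size_nc_pearson_r"] = round(size_nc_correlation(corr_rows), 4)
    else:
        logger.warning("fewer than 3 genomes: correlation skipped")
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(cfg, out, "stats")
    return out / "noncoding.tsv"


def run_elongate(
    cfg: PipelineConfig, fastq_in: str | Path, bait_fasta: str | Path
) -> Path:
    """Seed from a bait, extend, circularize; write FASTA plus a coverage report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = read_fastq(fastq_in)
    bait = next(iter(_load_refs(bait_fasta).values()))
    seed = find_seed(reads, bait)
    genome, contig = elongate_and_circularize(
        seed, reads,
        min_overlap=cfg.min_overlap,
        min_end_overlap=cfg.min_end_overlap,
        max_rounds=cfg.max_rounds,
    )
    report: dict = {
        "circular": genome is not None,
        "contig_length": contig.length,
        "rounds": contig.rounds_applied,
    }
    if genome is not None:
        write_fasta([genome], out / "assembly.fasta")
        cov = coverage_stats(genome, reads, cfg.min_overlap)
        report["genome_length"] = genome.length
        report["coverage"] = {
            "mean": round(cov.mean, 1), "sd": round(cov.sd, 1),
            "min": cov.min, "max": cov.max, "unplaced_reads": cov.unplaced_reads,
        }
    else:
        write_fasta([MitoGenome("contig", contig.sequence)], out / "assembly.fasta")
    (out / "elongate_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_manifest(cfg, out, "elongate")
    return out / "assembly.fasta"


def run_simulate(cfg: PipelineConfig, spec_yaml: str | Path | None = None) -> Path:
    """Generate a synthetic genome (+ annotation, reads, truth ledger)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec_yaml:
        with open(spec_yaml) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gene_models", "nc_tract_lengths", "urf_aa_range", "planted_repeat"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x for x in raw[key]) \
                    if key == "gene_models" else tuple(raw[key])
        spec = GenomeSpec(**raw)
    else:
        spec = GenomeSpec(seed=cfg.seed)
    genome, ann, ledger = generate_genome(spec)
    write_fasta([genome], out / f"{genome.id}.fasta")
    write_genbank(genome, ann, out / f"{genome.id}.gb")
    reads, read_ledger = simulate_reads(genome, depth=30, seed=spec.seed)
    from .io import write_fastq

    write_fastq(reads, out / f"{genome.id}.fastq")
    ledger.read_params = read_ledger.read_params
    (out / f"{genome.id}.truth.json").write_text(ledger.to_json())
    _write_manifest(cfg, out, "simulate")
    return out / f"{genome.id}.fasta"
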