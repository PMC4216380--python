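"""End-to-end orchestration: QC -> multi-k assembly -> search -> annotation
-> core-transcript QC -> peptide mass table, with a provenance manifest.

A run is described by one YAML config; all randomness flows from a single
global seed and a rerun with an identical config reproduces identical
outputs.  Each stage records its parameters and the SHA-256 of every file
it writes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import assembler, assembly_qc, peptide_mass, precursor_annotator, read_qc

logger = logging.getLogger("seedfam")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    reads1: str
    reads2: str
    query_fasta: str
    reference_fasta: str
    reference_regions: dict
    outdir: str
    core_genes_fasta: Optional[str] = None
    core_genes_tsv: Optional[str] = None
    observed_masses: Optional[str] = None
    k_list: list = field(default_factory=lambda: [23, 60])
    qc: dict = field(default_factory=dict)
    min_contig_length: int = 300
    bubble_size: int = 50
    scaffold: bool = False
    min_score: float = 40.0
    mass_tolerance: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.k_list:
            raise ConfigError("k_list must be non-empty")
        for key in ("reads1", "reads2", "query_fasta", "reference_fasta"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        for key in ("core_genes_fasta", "core_genes_tsv", "observed_masses"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    A stage failure is recorded in the manifest, downstream stages are
    skipped, and the manifest carries status 'failed'.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()}, "stages": [], "outputs": {}}
    state: dict = {}

    stages = [
        ("qc", _stage_qc),
        ("assemble", _stage_assemble),
        ("annotate", _stage_annotate),
        ("qcsuite", _stage_qcsuite),
        ("mass", _stage_mass),
        ("report", _stage_report),
    ]
    failed = False
    for name, fn in stages:
        entry = {"stage": name, "status": "skipped"}
        if not failed:
            t0 = time.time()
            try:
                fn(config, outdir, state)
                entry["status"] = "completed"
            except Exception as exc:  # stage failure is a run failure
                logger.exception("stage %s failed", name)
                entry["status"] = "failed"
                entry["error"] = str(exc)
                failed = True
            entry["seconds"] = round(time.time() - t0, 3)
        manifest["stages"].append(entry)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    manifest["status"] = "failed" if failed else "ok"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_qc(config: RunConfig, outdir: Path, state: dict) -> None:
    params = read_qc.QCParams(**config.qc) if config.qc else read_qc.QCParams()
    r1 = read_qc.read_fastq(config.reads1, mate="first")
    r2 = read_qc.read_fastq(config.reads2, mate="second")
    pairs, _, report = read_qc.qc_pipeline(r1, r2, params, mode="per_mate_paired")
    state["pairs"] = pairs
    state["clean_reads"] = [r for p in pairs for r in p]
    read_qc.write_report(report, json_path=outdir / "qc_report.json", tsv_path=outdir / "qc_report.tsv")
    logger.info("qc: %d raw -> %d clean reads", report.raw_count, report.clean_count)


def _stage_assemble(config: RunConfig, outdir: Path, state: dict) -> None:
    params = assembler.AssemblyParams(
        min_contig_length=max(config.min_contig_length, max(config.k_list)),
        bubble_size=config.bubble_size,
        use_pairs=True,
        scaffold=config.scaffold,
    )
    assemblies = assembler.multi_k_assemble(
        state["clean_reads"], config.k_list, params, pairs=state["pairs"]
    )
    state["assemblies"] = assemblies
    rows = []
    for k, asm in assemblies.items():
        assembler.write_fasta(asm.contigs, outdir / f"contigs_k{k}.fasta")
        rows.append((k, asm.stats))
    state["assembly_rows"] = rows
    state["union"] = assembler.union_contigs(assemblies)
    assembler.write_fasta(state["union"], outdir / "contigs_union.fasta")


def _stage_annotate(config: RunConfig, outdir: Path, state: dict) -> None:
    query = assembler.read_fasta(config.query_fasta)[0][1]
    reference = assembler.read_fasta(config.reference_fasta)[0][1]
    regions = {k: tuple(v) for k, v in config.reference_regions.items()}
    anns = precursor_annotator.mine_transcriptome(
        state["union"], query, reference, regions, min_score=config.min_score
    )
    state["annotations"] = anns
    precursor_annotator.write_annotation_tsv(anns, outdir / "annotations.tsv")


def _stage_qcsuite(config: RunConfig, outdir: Path, state: dict) -> None:
    if not config.core_genes_fasta:
        state["qc_rows"], state["verdict"] = [], None
        return
    tiers = {}
    if config.core_genes_tsv:
        with open(config.core_genes_tsv) as fh:
            next(fh)
            for line in fh:
                name, tier = line.split("\t")[:2]
                tiers[name] = float(tier)
    core = [
        assembly_qc.CoreGene(name, seq, tiers.get(name, 0.0))
        for name, seq in assembler.read_fasta(config.core_genes_fasta)
    ]
    rows, verdict = assembly_qc.core_suite_report(
        state["union"], state["clean_reads"], core, min_score=config.min_score
    )
    state["qc_rows"], state["verdict"] = rows, verdict
    assembly_qc.write_qc_tsv(rows, outdir / "core_suite.tsv", verdict)


def _stage_mass(config: RunConfig, outdir: Path, state: dict) -> None:
    table = peptide_mass.predict_pdp_ion_table(state["annotations"])
    state["mass_table"] = table
    table.to_csv(outdir / "pdp_masses.tsv", sep="\t", index=False)
    if config.observed_masses:
        observed = peptide_mass.read_observed_masses(config.observed_masses)
        matches, n = peptide_mass.match_observed(table, observed, config.mass_tolerance)
        state["mass_matches"] = (matches, n)
        with open(outdir / "mass_matches.tsv", "w") as fh:
            fh.write("sequence\tpredicted_mz\tobserved_mz\tdelta\twithin_tolerance\n")
            for m in matches:
                fh.write(
                    f"{m.sequence}\t{m.predicted_mz}\t{m.observed_mz}\t"
                    f"{m.delta}\t{m.within_tolerance}\n"
                )


def _stage_report(config: RunConfig, outdir: Path, state: dict) -> None:
    with open(outdir / "assembly_stats.tsv", "w") as fh:
        fh.write("word_size\tn50\tcontig_count\ttotal_bases\n")
        for k, stats in state["assembly_rows"]:
            fh.write(f"{k}\t{stats.n50}\t{stats.contig_count}\t{stats.total_bases}\n")
    anns = state.get("annotations", [])
    lines = ["# Run summary", ""]
    if anns:
        lines.append(f"{len(anns)} candidate precursor transcript(s) annotated:")
        for a in anns:
            lines.append(
                f"- {a.orf.contig_id}: {a.class_label} ({a.confidence}), "
                f"PDP {a.pdp_sequence or 'absent'}"
            )
    else:
        lines.append("no target transcripts found")
    if state.get("verdict") is not None:
        lines.append("")
        lines.append(
            "core-transcript verdict: "
            + ("low-abundance-capable" if state["verdict"] else "low-abundance genes NOT captured")
        )
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
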