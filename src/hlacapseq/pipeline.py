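"""End-to-end orchestration: simulate -> genotype -> quantify -> stats.

Each stage persists plain-text intermediates (FASTQ/TSV/JSON) so any stage
can be re-run independently; outputs are deterministic under a fixed seed,
which is echoed in the run report together with the configuration.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .genotype import GenotypeCall, call_genotype, match_reads
from .quantify import (
    SampleQuant,
    build_dataset,
    locus_set,
    quantify_sample,
)
from .reference import (
    Locus,
    ReferenceSet,
    load_reference_set,
    write_reference_set,
)
from .simulate import (
    SimConfig,
    emit_reads,
    simulate_expression,
    simulate_genotypes,
    synthesize_panel,
)
from .stats import allele_summary_table, locus_summary_table

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "load_paired_fastq",
    "genotype_sample",
    "read_config",
]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(ValueError):
    """Input data failed validation or parsing."""


def load_paired_fastq(r1: str | Path, r2: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ pair into ``(mate_id, sequence)`` tuples.

    Mate ids keep their ``/1``/``/2`` suffix (or gain one) so mates remain
    distinct reads; genotyping strips the suffix to deduplicate support per
    pair.
    """
    out: list[tuple[str, str]] = []
    for path, mate in ((Path(r1), 1), (Path(r2), 2)):
        if not path.exists():
            raise DataError(f"FASTQ file not found: {path}")
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                plus = fh.readline()
                qual = fh.readline()
                if not header.startswith("@") or not plus.startswith("+") or not qual:
                    raise DataError(f"malformed FASTQ record in {path}")
                name = header[1:].split()[0].rstrip("\n")
                if not name.endswith(f"/{mate}"):
                    name = f"{name}/{mate}"
                out.append((name, seq.upper()))
    return out


def pair_id(mate_id: str) -> str:
    return mate_id[:-2] if mate_id.endswith(("/1", "/2")) else mate_id


def genotype_sample(
    reads: Sequence[tuple[str, str]],
    panel: ReferenceSet,
    min_unique_support: int = 10,
) -> tuple[dict[Locus, GenotypeCall], pd.DataFrame]:
    """Match mates independently, deduplicate support per pair, call per locus."""
    pair_reads = [(pair_id(rid), seq) for rid, seq in reads]
    hits = match_reads(pair_reads, panel)
    calls = {
        locus: call_genotype(hits, locus, min_unique_support=min_unique_support)
        for locus in panel.loci
    }
    return calls, hits


@dataclass
class PipelineConfig:
    """Run configuration (parsed from YAML or built directly)."""

    out_dir: Path
    seed: int = 0
    panel_fasta: Path | None = None
    panel_annotation: Path | None = None
    simulate: dict | None = None
    reads: Mapping[str, tuple[Path, Path]] = dc_field(default_factory=dict)
    sets: tuple[int, ...] = (1, 2, 3, 4)
    min_unique_support: int = 10
    min_n: int = 3
    split_ambiguous: bool = False

    def validate(self) -> None:
        if self.simulate is None and self.panel_fasta is None:
            raise ConfigError("either a panel (fasta+annotation) or a simulate block is required")
        for p in (self.panel_fasta, self.panel_annotation):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")
        for sample, (r1, r2) in self.reads.items():
            for p in (r1, r2):
                if not Path(p).exists():
                    raise ConfigError(f"reads for sample {sample}: missing {p}")
        for s in self.sets:
            if s not in (1, 2, 3, 4):
                raise ConfigError(f"unknown locus set id {s}")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        reads = {
            sample: (Path(r1), Path(r2))
            for sample, (r1, r2) in (raw.get("reads") or {}).items()
        }
        return PipelineConfig(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            panel_fasta=Path(raw["panel"]["fasta"]) if raw.get("panel") else None,
            panel_annotation=(
                Path(raw["panel"]["annotation"]) if raw.get("panel") else None
            ),
            simulate=raw.get("simulate"),
            reads=reads,
            sets=tuple(raw.get("sets", (1, 2, 3, 4))),
            min_unique_support=int(raw.get("min_unique_support", 10)),
            min_n=int(raw.get("min_n", 3)),
            split_ambiguous=bool(raw.get("split_ambiguous", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


@dataclass
class RunReport:
    seed: int
    config_hash: str
    stages: dict = dc_field(default_factory=dict)
    counts: dict = dc_field(default_factory=dict)

    def log(self, out_dir: Path, event: str, **fields) -> None:
        record = {"event": event, "seed": self.seed, "config": self.config_hash, **fields}
        with open(out_dir / "run.log.jsonl", "a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "stages": self.stages,
            "counts": self.counts,
        }


def _sim_config(block: dict, seed: int) -> tuple[list[Locus], int, int, SimConfig]:
    loci = [Locus(l) for l in block.get("loci", [l.value for l in Locus])]
    alleles_per_locus = int(block.get("alleles_per_locus", 4))
    divergence = int(block.get("divergence", 3))
    sim = SimConfig(
        n_samples=int(block.get("n_samples", 6)),
        depth=int(block.get("depth", 2000)),
        error_rate=float(block.get("error_rate", 0.001)),
        capture_bias_sigma=float(block.get("capture_bias_sigma", 0.1)),
        seed=seed,
    )
    return loci, alleles_per_locus, divergence, sim


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; stage outputs are written even on later failure."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        repr(sorted(config.__dict__.items(), key=lambda kv: kv[0])).encode()
    ).hexdigest()[:12]
    report = RunReport(seed=config.seed, config_hash=cfg_hash)
    t0 = time.time()

    # --- stage: panel / simulate -------------------------------------------
    reads_by_sample: dict[str, tuple[Path, Path]] = dict(config.reads)
    if config.simulate is not None:
        loci, per_locus, divergence, sim = _sim_config(config.simulate, config.seed)
        panel = synthesize_panel(loci, per_locus, divergence, seed=config.seed)
        write_reference_set(panel, out_dir / "panel.fasta", out_dir / "panel.tsv")
        genotypes = simulate_genotypes(panel, sim.n_samples, seed=sim.seed)
        genotypes.to_csv(out_dir / "sim_genotypes.tsv", sep="\t", index=False)
        truth = simulate_expression(genotypes, sim)
        reads_dir = out_dir / "reads"
        fastqs = emit_reads(truth, panel, sim, reads_dir)
        reads_by_sample.update(fastqs)
        report.stages["simulate"] = {
            "n_samples": sim.n_samples,
            "n_alleles": len(panel),
            "depth": sim.depth,
        }
        report.log(out_dir, "simulate.done", n_samples=sim.n_samples)
    else:
        panel = load_reference_set(config.panel_fasta, config.panel_annotation)
        report.stages["panel"] = {"n_alleles": len(panel)}

    if not reads_by_sample:
        raise ConfigError("no reads: provide a reads mapping or a simulate block")

    # --- stage: genotype ----------------------------------------------------
    genotype_rows = []
    sample_quants: list[SampleQuant] = []
    total_in = total_matched = total_inphase = 0
    for sample_id in sorted(reads_by_sample):
        r1, r2 = reads_by_sample[sample_id]
        reads = load_paired_fastq(r1, r2)
        calls, hits = genotype_sample(
            reads, panel, min_unique_support=config.min_unique_support
        )
        matched_pairs = set(hits["read_id"])
        n_matched = sum(1 for rid, _ in reads if pair_id(rid) in matched_pairs)
        total_in += len(reads)
        total_matched += n_matched
        for locus, call in sorted(calls.items(), key=lambda kv: kv[0].value):
            pair = [n.render() for n in call.allele_pair]
            support = [call.support.get(n, 0) for n in pair]
            genotype_rows.append(
                {
                    "sample_id": sample_id,
                    "locus": locus.value,
                    "allele1": pair[0] if pair else "",
                    "allele2": pair[1] if len(pair) > 1 else "",
                    "zygosity": call.zygosity,
                    "support1": support[0] if support else 0,
                    "support2": support[1] if len(support) > 1 else 0,
                    "ambiguity": ";".join("/".join(t) for t in call.ambiguity_note),
                }
            )
        sq = quantify_sample(
            sample_id, reads, calls, panel, split_ambiguous=config.split_ambiguous
        )
        total_inphase += int(sum(q.raw_reads for q in sq.counts))
        sample_quants.append(sq)
        report.log(out_dir, "sample.done", sample=sample_id, reads=len(reads))

    pd.DataFrame(genotype_rows).to_csv(out_dir / "genotypes.tsv", sep="\t", index=False)
    with open(out_dir / "qc.json", "w") as fh:
        json.dump([sq.qc_record() for sq in sample_quants], fh, indent=2, sort_keys=True)
    report.counts.update(
        reads_in=total_in,
        reads_matched=total_matched,
        reads_unmatched=total_in - total_matched,
        reads_in_phase=total_inphase,
    )
    report.stages["genotype"] = {"n_samples": len(sample_quants)}

    # --- stage: quantify ----------------------------------------------------
    tables = []
    for set_id in config.sets:
        table = build_dataset(sample_quants, locus_set(set_id))
        tables.append(table)
    counts = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    counts.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
    report.stages["quantify"] = {
        "n_rows": int(len(counts)),
        "sets": list(config.sets),
    }

    # --- stage: stats -------------------------------------------------------
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    for set_id in config.sets:
        sub = counts[counts["set_id"] == set_id] if len(counts) else counts
        if len(sub) == 0:
            continue
        locus_summary_table(sub).to_csv(
            stats_dir / f"set{set_id}_locus_summary.tsv", sep="\t", index=False
        )
        allele_summary_table(sub, min_n=config.min_n).to_csv(
            stats_dir / f"set{set_id}_allele_summary.tsv", sep="\t", index=False
        )
    report.stages["stats"] = {"sets": list(config.sets)}

    report.stages["elapsed_s"] = round(time.time() - t0, 2)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=2, sort_keys=True)
    report.log(out_dir, "pipeline.done")
    return report
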