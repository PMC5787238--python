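"""End-to-end orchestration: build-db -> prep -> profile -> resolve.

A single ``RunConfig`` holds every path and parameter; ``run_end_to_end``
executes the stages in order, persists every intermediate artifact under the
output directory, and writes a JSON manifest sufficient to re-execute the
run bit-identically (config snapshot, input checksums, per-stage record
counts, stage timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .read_processing import (
    DEFAULT_MIN_READ_FRACTION,
    QualityFilterParams,
    ReadTable,
    prepare_reads,
    write_filter_report,
)
from .profiling_core import EM_MAX_ITER, EM_TOL, ErrorModel, profile
from .reference_db import (
    ReferenceSet,
    RegionKmerDb,
    build_region_kmer_db,
    default_primer_set,
    load_primers,
)
from .resolution_analysis import (
    DEFAULT_MIN_GROUP_FREQUENCY,
    ambiguity_by_label,
    assign_groups,
    postprocess_profile,
    write_groups_tsv,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Paths and parameters for one profiling run.

    Defaults follow the published protocol: per-base error probability
    0.005, two-mismatch caps for primer and read matching, a 1e-4
    low-frequency read filter, and a 0.1% group-frequency floor.
    """

    reference_fasta: str = ""
    taxonomy: str | None = None
    primers: str | None = None          # None -> packaged six-pair set
    fastq: str = ""
    fastq2: str | None = None
    output_dir: str = "smurf_out"
    read_len: int = 75
    mode: str = "paired"
    p_e: float = 0.005
    primer_mismatch_cap: int = 2
    read_mismatch_cap: int = 2
    min_read_fraction: float = DEFAULT_MIN_READ_FRACTION
    min_group_frequency: float = DEFAULT_MIN_GROUP_FREQUENCY
    taxonomy_level: str = "species"
    barcode_len: int = 0
    tol: float = EM_TOL
    max_iter: int = EM_MAX_ITER
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, dict] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        tmp.replace(path)  # atomic publish


def run_end_to_end(config: RunConfig):
    """Execute the full pipeline and persist all artifacts.

    Returns (ProfileResult, groups, AmbiguityReport, RunManifest).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    checksums = {}
    for label, p in (
        ("reference_fasta", config.reference_fasta),
        ("taxonomy", config.taxonomy),
        ("primers", config.primers),
        ("fastq", config.fastq),
        ("fastq2", config.fastq2),
    ):
        if p:
            checksums[label] = _sha256(p)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        input_checksums=checksums,
    )

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_.t0, 4
                )
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("build_db"):
        ref = ReferenceSet.from_fasta(config.reference_fasta, config.taxonomy)
        primers = (
            load_primers(config.primers) if config.primers
            else default_primer_set()
        )
        db = build_region_kmer_db(
            ref, primers, k=config.read_len, mode=config.mode,
            mismatch_cap=config.primer_mismatch_cap,
        )
        db.save(out / "db")
        manifest.stage_counts["build_db"] = {
            "J": db.J, "H": db.H, "regions": db.region_ids,
            "discarded_ambiguous": ref.n_discarded_ambiguous,
        }

    with stage("prep"):
        reads = prepare_reads(
            config.fastq, primers, fastq2=config.fastq2,
            read_len=config.read_len, barcode_len=config.barcode_len,
            quality_params=QualityFilterParams(),
            primer_mismatch_cap=config.primer_mismatch_cap,
            min_fraction=config.min_read_fraction,
        )
        reads.to_tsv(out / "reads.tsv")
        write_filter_report(reads, out / "filter_report.json")
        manifest.stage_counts["prep"] = {
            "per_region": {str(r): reads.n(r) for r in reads.region_ids},
            "discarded": reads.discarded,
        }
        empty = [r for r in reads.region_ids if reads.n(r) == 0]
        if not reads.region_ids or reads.total == 0:
            raise ValueError("no reads survived preparation")
        if empty:
            raise ValueError(f"regions with zero retained reads: {empty}")

    with stage("profile"):
        result = profile(
            reads, db,
            ErrorModel(p_e=config.p_e, mismatch_cap=config.read_mismatch_cap),
            tol=config.tol, max_iter=config.max_iter,
        )
        result.to_tsv(out / "profile.tsv")
        (out / "likelihood_trace.tsv").write_text(
            "\n".join(f"{v:.10g}" for v in result.log_likelihood) + "\n"
        )
        manifest.stage_counts["profile"] = {
            "n_candidates": len(result.taxon_ids),
            "n_supported": int((result.x > 0).sum()),
            "n_iter": result.n_iter,
            "converged": result.converged,
        }

    with stage("resolve"):
        groups = assign_groups(result, db)
        write_groups_tsv(groups, out / "groups.tsv")
        report = ambiguity_by_label(groups, config.taxonomy_level)
        report.to_tsv(out / "ambiguity.tsv")
        merged = postprocess_profile(
            groups, config.min_group_frequency, config.taxonomy_level
        )
        with open(out / "merged_profile.tsv", "w") as fh:
            fh.write("label\tfrequency\tn_groups\tmember_ids\n")
            for e in merged:
                fh.write(
                    f"{e.label}\t{e.frequency:.10g}\t{e.n_groups}\t"
                    f"{','.join(e.member_ids)}\n"
                )
        manifest.stage_counts["resolve"] = {
            "n_groups": len(groups),
            "n_merged": len(merged),
            "mean_ambiguity": report.mean_ambiguity,
        }

    manifest.save(out / "manifest.json")
    return result, groups, report, manifest
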