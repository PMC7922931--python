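"""End-to-end orchestration: recruit -> peak-filter -> normalize -> cluster,
and fixtures -> consortium validation/design -> biostimulant ranking.

Each run writes its stage outputs plus a JSON manifest (parameters, seed,
per-stage read counts) into one output directory.  Files are written to a
temporary name and renamed into place, so a crashed run leaves no
half-written stage output under the final name.  Reruns with an identical
config produce byte-identical TSV/CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import aggregate_by_environment, autoscale_rows, per_sample_matrix, plot_heatmap
from .biostimulant import BiostimulantTable, rank_compounds
from .consortium import enumerate_consortia, validate_consortium
from .coverage_filter import compute_coverage, filter_recruited_reads, locus_mask
from .io_formats import (
    load_published_tables,
    read_fasta,
    read_fastq,
    read_sample_metadata,
    write_hits_tsv,
)
from .recruiter import RecruitmentParams, recruit_sample

logger = logging.getLogger(__name__)

#: function tags the published consortia were designed to cover
DEFAULT_REQUIRED_FUNCTIONS = (
    "nitrogen_fixation",
    "P_solubilization",
    "biocontrol",
    "amylolytic",
    "IAA_production",
)


@dataclass
class RecruitmentRunConfig:
    refs_fasta: str
    metadata_tsv: str
    fastq_dir: str
    out_dir: str
    params: RecruitmentParams = field(default_factory=RecruitmentParams)
    autoscale: bool = True
    heatmap: bool = True
    seed: int = 0


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_to_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, **kwargs)
    os.replace(tmp, path)


def run_recruitment_pipeline(config: RecruitmentRunConfig) -> dict:
    """Recruit every sample, peak-filter, normalize, cluster; return the manifest.

    Expects ``{fastq_dir}/{sample_id}.fastq`` (``.gz`` tolerated) for every
    sample listed in the metadata TSV.  Missing inputs abort before any
    compute.
    """
    out = Path(config.out_dir)
    refs_path, meta_path, fastq_dir = (
        Path(config.refs_fasta),
        Path(config.metadata_tsv),
        Path(config.fastq_dir),
    )
    for p in (refs_path, meta_path, fastq_dir):
        if not p.exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    metadata = read_sample_metadata(meta_path)
    fastqs = {}
    for m in metadata:
        for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
            candidate = fastq_dir / f"{m.sample_id}{suffix}"
            if candidate.exists():
                fastqs[m.sample_id] = candidate
                break
        else:
            raise FileNotFoundError(f"no FASTQ found for sample {m.sample_id} in {fastq_dir}")
    out.mkdir(parents=True, exist_ok=True)

    genomes = read_fasta(refs_path)
    manifest = {
        "tool": "pgpmkit",
        "version": __version__,
        "stage": "recruitment",
        "seed": config.seed,
        "params": asdict(config.params),
        "genomes": [g.id for g in genomes],
        "samples": {},
    }
    raw_counts = pd.DataFrame(
        0, index=[g.id for g in genomes], columns=[m.sample_id for m in metadata]
    )
    peak_rows = []
    for m in metadata:
        reads = read_fastq(fastqs[m.sample_id], max_reads=config.params.max_reads)
        rec = recruit_sample(reads, genomes, config.params)
        all_hits, qualified_hits = [], []
        sample_counts = {}
        for g in genomes:
            hits = rec.hits[g.id]
            profile = compute_coverage(hits, genome_id=g.id)
            qualified = filter_recruited_reads(hits, profile) if hits else []
            mask = locus_mask(profile)
            for locus, ok in sorted(mask.qualified.items()):
                if not ok:
                    peak_rows.append(
                        (m.sample_id, g.id, locus, profile.counts[locus],
                         round(mask.threshold, 4), profile.counts[locus])
                    )
            all_hits.extend(hits)
            qualified_hits.extend(qualified)
            raw_counts.loc[g.id, m.sample_id] = len(qualified)
            sample_counts[g.id] = {"recruited": len(hits), "qualified": len(qualified)}
        write_hits_tsv(all_hits, out / f"{m.sample_id}.hits.tsv")
        write_hits_tsv(qualified_hits, out / f"{m.sample_id}.hits.qualified.tsv")
        manifest["samples"][m.sample_id] = {
            "environment": m.environment,
            "total_reads": m.total_reads,
            "reads_considered": rec.n_reads,
            "skipped_short": rec.n_skipped_short,
            "recruited": len(all_hits),
            "removed_by_peak_filter": len(all_hits) - len(qualified_hits),
            "qualified": len(qualified_hits),
            "per_genome": sample_counts,
        }
    pd.DataFrame(
        peak_rows,
        columns=["sample_id", "genome_id", "locus", "count", "threshold", "removed_reads"],
    ).pipe(_atomic_to_csv, out / "peaks.tsv", sep="\t", index=False)

    per_sample = per_sample_matrix(raw_counts, metadata)
    _atomic_to_csv(per_sample, out / "matrix.samples.tsv", sep="\t")
    by_env = aggregate_by_environment(raw_counts, metadata)
    _atomic_to_csv(by_env, out / "matrix.environments.tsv", sep="\t")
    if config.autoscale:
        _atomic_to_csv(autoscale_rows(per_sample), out / "matrix.samples.autoscaled.tsv", sep="\t")
    if config.heatmap and per_sample.shape[0] >= 2 and per_sample.shape[1] >= 2:
        plot_heatmap(per_sample, out / "heatmap.samples.png")
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_consortium_pipeline(
    out_dir,
    fixture_dir=None,
    policy: str = "lenient",
    required_functions=DEFAULT_REQUIRED_FUNCTIONS,
    size_range: tuple[int, int] = (5, 25),
    strict_missing: bool = False,
) -> dict:
    """Validate the published consortia, enumerate candidates, rank compounds.

    Writes one validation report per packaged consortium, a candidate list
    from maximal-clique enumeration over the selected strains, and the
    biostimulant ranking per consortium; returns everything as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = load_published_tables(fixture_dir)
    required = set(required_functions or ())

    reports = {}
    for name, consortium in sorted(tables.consortia.items()):
        report = validate_consortium(
            consortium,
            tables.compat,
            strain_table=tables.strains,
            required_functions=required,
            strict_missing=strict_missing,
        )
        reports[name] = report.to_dict()
        _atomic_write_text(
            out / f"validation_{name}.json", json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )

    candidates = enumerate_consortia(
        tables.strains,
        tables.compat,
        required_functions=required,
        size_range=size_range,
        policy=policy,
    )
    cand_df = pd.DataFrame(
        [(c.name, len(c.members), ";".join(c.members)) for c in candidates],
        columns=["candidate", "size", "members"],
    )
    _atomic_to_csv(cand_df, out / "candidates.csv", index=False)

    bios = BiostimulantTable(tables.biostimulants)
    rankings = {}
    for name, consortium in sorted(tables.consortia.items()):
        rankings[name] = [
            {
                "compound": s.compound,
                "fraction_positive": s.fraction_positive,
                "breakdown": s.breakdown,
            }
            for s in rank_compounds(consortium, bios)
        ]
    _atomic_write_text(
        out / "biostimulant_rankings.json", json.dumps(rankings, indent=2, sort_keys=True)
    )
    result = {
        "policy": policy,
        "validation": reports,
        "n_candidates": len(candidates),
        "rankings": rankings,
    }
    logger.info(
        "consortium pipeline: %d reports, %d candidates", len(reports), len(candidates)
    )
    return result
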