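"""Configuration-driven orchestration of the full analysis.

Two entry points mirror the study design: ``run_disease_comparison`` takes
a window count matrix plus sample disease labels and produces the
per-window test table, DMR table, threshold sweep, cluster list and PCA
scores for one disease; ``run_cohort_summary`` reproduces the pathology
table statistics (affected/evaluated per disease, multiple-disease tally,
Fisher tests of lineage contrasts).  Both write plain TSV/JSON artifacts
plus a manifest recording versions, the configuration hash and input
checksums, and are deterministic given the configuration seed.

``disease_comparison`` is the in-memory core used by the file-based runner
and by tests; the CLI is a thin wrapper over this module.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import WindowCountMatrix, rpkm
from .differential import (
    DispersionModel,
    GroupDesign,
    estimate_common_dispersion,
    results_to_frame,
    test_all_windows,
    tmm_norm_factors,
)
from .dmr import (
    DEFAULT_SWEEP,
    characterize,
    dmrs_to_frame,
    extend_and_merge,
    find_clusters,
    select_seeds,
    threshold_sweep,
)
from .pathology import (
    DISEASE_NAMES,
    fisher_exact_2x2,
    read_animal_records,
    summarize_cohort,
)
from .pca import fit_pca, separation_score

__all__ = [
    "PipelineConfig",
    "ComparisonResult",
    "disease_comparison",
    "run_disease_comparison",
    "run_cohort_summary",
    "read_fasta",
]


@dataclass
class PipelineConfig:
    output_dir: Path
    counts_path: Path | None = None
    metadata_path: Path | None = None
    genome_fasta: Path | None = None
    genes_path: Path | None = None
    records_path: Path | None = None
    window_bp: int = 100
    seed_p: float = 1e-5
    edge_p: float = 0.1
    gap_bp: int = 1000
    gene_distance_bp: int = 10_000
    fdr_alpha: float = 0.1
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_p", "edge_p", "fdr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gap_bp <= 0 or self.gene_distance_bp <= 0 or self.window_bp <= 0:
            raise ValueError("distances must be positive")

    def config_hash(self) -> str:
        d = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ComparisonResult:
    disease_name: str
    results: list
    dmrs: list
    sweep: pd.DataFrame
    clusters: list
    pca_model: object | None
    silhouette: float | None


def disease_comparison(
    matrix: WindowCountMatrix,
    labels: Mapping[str, bool],
    disease_name: str = "disease",
    genome: Mapping[str, str] | None = None,
    genes: pd.DataFrame | None = None,
    seed_p: float = 1e-5,
    edge_p: float = 0.1,
    gap_bp: int = 1000,
    gene_distance_bp: int = 10_000,
    sweep_thresholds: Sequence[float] = DEFAULT_SWEEP,
    run_pca: bool = True,
) -> ComparisonResult:
    """Full two-group comparison for one disease, in memory."""
    n_with = sum(1 for v in labels.values() if v)
    n_without = len(labels) - n_with
    if n_with < 2 or n_without < 2:
        raise ValueError(
            f"{disease_name}: need >=2 samples per group "
            f"(got {n_with} with, {n_without} without)"
        )
    design = GroupDesign.from_labels(labels)
    factors = tmm_norm_factors(matrix)
    phi = estimate_common_dispersion(matrix, design, factors)
    model = DispersionModel(common_dispersion=phi, norm_factors=factors)
    results = test_all_windows(matrix, design, model)
    seeds = select_seeds(results, seed_p)
    dmrs = extend_and_merge(seeds, results, edge_p=edge_p, gap_bp=gap_bp, seed_p=seed_p)
    if genome is not None:
        for d in dmrs:
            characterize(d, genome, genes, gene_distance_bp)
    sweep = threshold_sweep(results, sweep_thresholds, edge_p=edge_p, gap_bp=gap_bp)
    clusters = find_clusters(dmrs)
    pca_model = None
    sil = None
    if run_pca and dmrs and len(matrix.sample_ids) >= 3:
        rp = rpkm(matrix)
        member = [
            (w.chrom, w.start)
            for d in dmrs
            for w in d.member_windows
            if w.p_value < seed_p
        ]
        if len(member) >= 2:
            idx = [matrix.grid.window_index(c, s) for c, s in member]
            wids = [f"{c}:{s}" for c, s in member]
            pca_model = fit_pca(
                rp.values[idx, :].T, matrix.sample_ids, wids
            )
            sil = separation_score(
                pca_model.sample_scores,
                {s: ("disease" if labels[s] else "nondisease") for s in matrix.sample_ids},
            )
    return ComparisonResult(disease_name, results, dmrs, sweep, clusters, pca_model, sil)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(config: PipelineConfig, outdir: Path, inputs: Sequence[Path]) -> None:
    manifest = {
        "epimark_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input_checksums": {str(p): _checksum(p) for p in inputs if p is not None},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_disease_comparison(config: PipelineConfig, disease_name: str) -> ComparisonResult:
    """File-based disease comparison: reads counts/metadata, writes artifacts."""
    if config.counts_path is None or config.metadata_path is None:
        raise ValueError("counts_path and metadata_path are required")
    matrix = WindowCountMatrix.from_tsv(config.counts_path)
    meta = pd.read_csv(config.metadata_path, sep="\t")
    if disease_name not in meta.columns:
        raise ValueError(f"metadata has no column {disease_name!r}")
    labels = {
        str(r["sample_id"]): bool(int(r[disease_name])) for _, r in meta.iterrows()
    }
    labels = {s: labels[s] for s in matrix.sample_ids}
    genome = read_fasta(config.genome_fasta) if config.genome_fasta else None
    genes = (
        pd.read_csv(
            config.genes_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        if config.genes_path
        else None
    )
    res = disease_comparison(
        matrix,
        labels,
        disease_name,
        genome=genome,
        genes=genes,
        seed_p=config.seed_p,
        edge_p=config.edge_p,
        gap_bp=config.gap_bp,
        gene_distance_bp=config.gene_distance_bp,
        sweep_thresholds=config.sweep_thresholds,
    )
    outdir = Path(config.output_dir) / disease_name
    outdir.mkdir(parents=True, exist_ok=True)
    results_to_frame(res.results).to_csv(outdir / "window_tests.tsv", sep="\t", index=False)
    dmrs_to_frame(res.dmrs).to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    with open(outdir / "dmrs.bed", "w") as fh:
        for d in res.dmrs:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t0\t.\n")
    res.sweep.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)
    with open(outdir / "clusters.bed", "w") as fh:
        for chrom, s, e, n in res.clusters:
            fh.write(f"{chrom}\t{s}\t{e}\tcluster_n{n}\t0\t.\n")
    if res.pca_model is not None:
        rows = []
        for s, sc in res.pca_model.sample_scores.items():
            rows.append({"sample_id": s, "PC1": sc[0], "PC2": sc[1] if len(sc) > 1 else 0.0})
        pd.DataFrame(rows).to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"component": np.arange(1, len(res.pca_model.explained_variance) + 1),
             "explained_variance": res.pca_model.explained_variance}
        ).to_csv(outdir / "pca_explained_variance.tsv", sep="\t", index=False)
    _write_manifest(
        config,
        outdir,
        [p for p in (config.counts_path, config.metadata_path, config.genome_fasta, config.genes_path) if p],
    )
    return res


def run_cohort_summary(config: PipelineConfig) -> pd.DataFrame:
    """Cohort summary with per-disease Fisher tests for lineage contrasts."""
    if config.records_path is None:
        raise ValueError("records_path is required")
    records = read_animal_records(config.records_path)
    if not records:
        raise ValueError("empty cohort")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    lineages = sorted({r.lineage for r in records if r.lineage})
    frames = []
    for lin in lineages or [None]:
        subset = [r for r in records if lin is None or r.lineage == lin]
        summ = summarize_cohort(subset)
        df = summ.to_frame()
        df.insert(0, "lineage", lin or "all")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if len(lineages) == 2:
        a, b = lineages
        pvals = []
        for disease in out[out["lineage"] == a]["disease"]:
            ra = out[(out["lineage"] == a) & (out["disease"] == disease)].iloc[0]
            rb = out[(out["lineage"] == b) & (out["disease"] == disease)].iloc[0]
            p = fisher_exact_2x2(
                int(ra["affected"]),
                int(ra["evaluated"] - ra["affected"]),
                int(rb["affected"]),
                int(rb["evaluated"] - rb["affected"]),
            )
            pvals.append({"disease": disease, "fisher_p": p})
        pd.DataFrame(pvals).to_csv(outdir / "lineage_fisher.tsv", sep="\t", index=False)
    out.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    _write_manifest(config, outdir, [config.records_path])
    return out
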