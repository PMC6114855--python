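"""DMR construction from per-window test results.

Windows below a seed p-value threshold (1e-5 by default) nucleate DMRs.
Each DMR is then extended: any window with p below the edge threshold
(0.1) lying within the gap distance (1000 bp) of the current span is
absorbed, and absorption repeats until a fixed point; DMRs that come to
share windows or overlap are merged.  The fixed point of that span-closure
is exactly single-linkage clustering of the sub-threshold windows at the
gap distance, which is how it is computed here (the literal iterative
closure serves as the test oracle).

A characterized DMR carries the span, the number of windows significant at
the seed threshold, the minimum member p-value, CpG count and density from
the reference sequence, the fold change at the most extreme member window,
and any genes within the association distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import WindowTestResult

__all__ = [
    "DMR",
    "select_seeds",
    "extend_and_merge",
    "characterize",
    "count_cpg",
    "threshold_sweep",
    "find_clusters",
    "dmrs_to_frame",
]


@dataclass
class DMR:
    name: str
    chrom: str
    start: int  # 0-based internally
    end: int
    n_significant_windows: int
    min_p: float
    member_windows: list[WindowTestResult] = field(repr=False, default_factory=list)
    cpg_number: int | None = None
    cpg_density: float | None = None
    max_fold_change: float | None = None
    max_log2_fold_change: float | None = None
    genes_within_10kb: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def select_seeds(
    results: Sequence[WindowTestResult], p_threshold: float = 1e-5
) -> list[WindowTestResult]:
    """Windows with p strictly below the seed threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return [r for r in results if r.p_value < p_threshold]


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp separation between two half-open intervals (0 if they touch/overlap)."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def extend_and_merge(
    seeds: Sequence[WindowTestResult],
    all_results: Sequence[WindowTestResult],
    edge_p: float = 0.1,
    gap_bp: int = 1000,
    seed_p: float = 1e-5,
) -> list[DMR]:
    """Grow each seed into a DMR by absorbing nearby sub-threshold windows.

    A window with p < ``edge_p`` within ``gap_bp`` of the current span
    (separation between interval edges, inclusive) is absorbed; the
    closure runs until no such window remains, and DMRs sharing windows or
    overlapping are merged.  ``n_significant_windows`` counts member
    windows with p < ``seed_p``.  Names are {chrom}:{ordinal} in start
    order, assigned after merging.
    """
    if not seeds:
        return []
    seed_keys = {(s.chrom, s.start) for s in seeds}
    by_chrom: dict[str, list[WindowTestResult]] = {}
    for r in all_results:
        if r.p_value < edge_p or (r.chrom, r.start) in seed_keys:
            by_chrom.setdefault(r.chrom, []).append(r)
    for s in seeds:
        if not any(
            r.chrom == s.chrom and r.start == s.start for r in by_chrom.get(s.chrom, [])
        ):
            raise ValueError(f"seed {s.chrom}:{s.start} not among supplied results")
    dmrs: list[DMR] = []
    for chrom in sorted(by_chrom):
        cand = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        # single-linkage components at gap <= gap_bp
        comp: list[WindowTestResult] = [cand[0]]
        comp_end = cand[0].end
        components: list[list[WindowTestResult]] = []
        for r in cand[1:]:
            if r.start - comp_end <= gap_bp:
                comp.append(r)
                comp_end = max(comp_end, r.end)
            else:
                components.append(comp)
                comp = [r]
                comp_end = r.end
        components.append(comp)
        for members in components:
            if not any((m.chrom, m.start) in seed_keys for m in members):
                continue
            n_sig = sum(1 for m in members if m.p_value < seed_p)
            dmrs.append(
                DMR(
                    name="",
                    chrom=chrom,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    n_significant_windows=max(n_sig, 1),
                    min_p=min(m.p_value for m in members),
                    member_windows=list(members),
                )
            )
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    ordinal: dict[str, int] = {}
    for d in dmrs:
        ordinal[d.chrom] = ordinal.get(d.chrom, 0) + 1
        d.name = f"{d.chrom}:{ordinal[d.chrom]}"
    return dmrs


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotides on the forward strand (strand-symmetric)."""
    return sequence.upper().count("CG")


def characterize(
    dmr: DMR,
    genome: Mapping[str, str],
    gene_annotation: pd.DataFrame | None = None,
    gene_distance_bp: int = 10_000,
) -> DMR:
    """Fill CpG, fold-change and gene-association fields of a DMR in place.

    CpG number counts CG dimers whose two bases both lie inside the span;
    density is per 100 bp of span.  The reported fold change is the ratio
    at the member window with the largest absolute log2 ratio.  Gene
    association uses inter-interval distance <= ``gene_distance_bp``
    (0 when overlapping).
    """
    if dmr.chrom not in genome:
        raise ValueError(f"DMR chromosome {dmr.chrom!r} absent from genome")
    seq = genome[dmr.chrom]
    if dmr.end > len(seq):
        raise ValueError(f"DMR {dmr.name} extends past end of {dmr.chrom}")
    dmr.cpg_number = count_cpg(seq[dmr.start : dmr.end])
    dmr.cpg_density = dmr.cpg_number / (dmr.length / 100.0)
    if dmr.member_windows:
        extreme = max(
            dmr.member_windows, key=lambda m: abs(np.log2(m.fold_change_ratio))
        )
        dmr.max_fold_change = float(extreme.fold_change_ratio)
        dmr.max_log2_fold_change = float(np.log2(extreme.fold_change_ratio))
    if gene_annotation is not None:
        from .signature import associate_genes

        dmr.genes_within_10kb = associate_genes(
            [dmr], gene_annotation, max_distance_bp=gene_distance_bp
        )[dmr.name]
    return dmr


DEFAULT_SWEEP = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def threshold_sweep(
    results: Sequence[WindowTestResult],
    thresholds: Sequence[float] = DEFAULT_SWEEP,
    edge_p: float = 0.1,
    gap_bp: int = 1000,
) -> pd.DataFrame:
    """DMR counts per seed p-value threshold.

    The full seed/extend/merge pipeline is rerun at each threshold;
    ``multiple_window`` counts DMRs with at least two windows significant
    at that same threshold.
    """
    rows = []
    for thr in thresholds:
        seeds = select_seeds(results, thr)
        dmrs = extend_and_merge(seeds, results, edge_p=edge_p, gap_bp=gap_bp, seed_p=thr)
        rows.append(
            {
                "threshold": thr,
                "all_window": len(dmrs),
                "multiple_window": sum(1 for d in dmrs if d.n_significant_windows >= 2),
            }
        )
    return pd.DataFrame(rows)


def find_clusters(
    dmrs: Sequence[DMR], span_bp: int = 2_000_000, min_dmrs: int = 3
) -> list[tuple[str, int, int, int]]:
    """Genomic clusters of DMRs: single linkage of DMR starts at span_bp.

    Returns (chrom, start, end, n_dmrs) for every linked run of at least
    ``min_dmrs`` DMRs; cluster intervals never overlap.
    """
    out: list[tuple[str, int, int, int]] = []
    by_chrom: dict[str, list[DMR]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: d.start)
        run = [ds[0]]
        for d in ds[1:]:
            if d.start - run[-1].start <= span_bp:
                run.append(d)
            else:
                if len(run) >= min_dmrs:
                    out.append((chrom, run[0].start, max(x.end for x in run), len(run)))
                run = [d]
        if len(run) >= min_dmrs:
            out.append((chrom, run[0].start, max(x.end for x in run), len(run)))
    return out


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """Signature-list report table (1-based starts)."""
    return pd.DataFrame(
        {
            "name": [d.name for d in dmrs],
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start + 1 for d in dmrs],
            "length": [d.length for d in dmrs],
            "n_significant_windows": [d.n_significant_windows for d in dmrs],
            "min_p": [d.min_p for d in dmrs],
            "cpg_number": [d.cpg_number for d in dmrs],
            "cpg_density": [d.cpg_density for d in dmrs],
            "max_fold_change": [d.max_fold_change for d in dmrs],
            "max_log2_fold_change": [d.max_log2_fold_change for d in dmrs],
            "genes_within_10kb": [";".join(d.genes_within_10kb) for d in dmrs],
        }
    )
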