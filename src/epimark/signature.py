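"""Disease signature comparison: DMR overlap, gene association, categories.

Each disease comparison yields a signature set of DMRs.  Signatures are
compared by genomic-interval intersection (>= 1 bp): DMRs from any sets
that overlap, directly or through a chain of overlaps, form one overlap
group, and each group is assigned to the Venn cell given by the diseases
it contains.  Gene association uses inter-interval distance (gap length
between half-open intervals, 0 when overlapping) of at most 10 kb.
Functional categories come from a user-supplied gene -> category map;
genes absent from the map fall into an "unknown" bucket.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dmr import DMR

__all__ = [
    "SignatureSet",
    "overlap_sets",
    "associate_genes",
    "categorize_genes",
]


@dataclass
class SignatureSet:
    disease_name: str
    dmrs: list[DMR]

    def __post_init__(self) -> None:
        names = [d.name for d in self.dmrs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate DMR names in signature {self.disease_name!r}")


def overlap_sets(sets: Sequence[SignatureSet]) -> dict[frozenset, int]:
    """Venn-cell counts over overlap groups of DMRs from all signatures.

    Two DMRs overlap when their spans intersect by >= 1 bp; transitive
    chains are merged into one group.  The returned map sends each
    non-empty disease combination to the number of overlap groups whose
    members come from exactly that combination; values sum to the number
    of groups (the size of the union).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 signature sets")
    items = [
        (d.chrom, d.start, d.end, s.disease_name)
        for s in sets
        for d in s.dmrs
    ]
    cells: Counter = Counter()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, disease in items:
        by_chrom.setdefault(chrom, []).append((start, end, disease))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        group_diseases: set[str] = set()
        group_end = None
        for start, end, disease in ivs:
            if group_end is None or start < group_end:  # >=1 bp intersection
                group_diseases.add(disease)
                group_end = end if group_end is None else max(group_end, end)
            else:
                cells[frozenset(group_diseases)] += 1
                group_diseases = {disease}
                group_end = end
        if group_diseases:
            cells[frozenset(group_diseases)] += 1
    return dict(cells)


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def associate_genes(
    dmrs: Sequence[DMR],
    gene_annotation: pd.DataFrame,
    max_distance_bp: int = 10_000,
) -> dict[str, list[str]]:
    """Genes within ``max_distance_bp`` of each DMR (inclusive rule).

    ``gene_annotation`` needs columns chrom, start, end, name (BED-style,
    0-based half-open).  A malformed record raises with its identity.
    """
    for col in ("chrom", "start", "end", "name"):
        if col not in gene_annotation.columns:
            raise ValueError(f"gene annotation missing column {col!r}")
    bad = gene_annotation[gene_annotation["end"] <= gene_annotation["start"]]
    if len(bad):
        raise ValueError(f"malformed gene interval: {bad.iloc[0].to_dict()}")
    genes = gene_annotation
    out: dict[str, list[str]] = {}
    for d in dmrs:
        sub = genes[genes["chrom"] == d.chrom]
        hits = [
            str(row["name"])
            for _, row in sub.iterrows()
            if _interval_gap(d.start, d.end, int(row["start"]), int(row["end"]))
            <= max_distance_bp
        ]
        out[d.name] = sorted(hits)
    return out


def categorize_genes(
    gene_lists: Mapping[str, Sequence[str]] | Sequence[str],
    category_map: Mapping[str, str],
) -> dict[str, int]:
    """Tally functional categories for associated genes.

    Accepts either a flat gene list or per-DMR lists (flattened).  Genes
    missing from the map count under "unknown".
    """
    if isinstance(gene_lists, Mapping):
        genes = [g for lst in gene_lists.values() for g in lst]
    else:
        genes = list(gene_lists)
    counts: Counter = Counter()
    for g in genes:
        counts[category_map.get(g, "unknown")] += 1
    return dict(counts)
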