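"""Synthetic study generator: toy genome, MeDIP window counts, cohort.

Everything downstream of wet lab and read mapping is testable against this
module: it emits a small reference genome with CpG deserts and optional
CpG islands, a gene annotation, a window x sample count matrix with
disease-associated DMRs embedded at known locations, and a simulated
pathology cohort with observer abnormality scores.  All generators are
pure functions of (config, seed).

Count model
-----------
Counts are negative binomial with Var = mu + phi * mu**2.  Two coverage
models are provided:

* ``"cpg"`` (default): MeDIP is an immunoprecipitation, so read depth
  concentrates in methylated CpG-bearing loci while the rest of the genome
  receives only a small nonspecific background (at real depths -- tens of
  millions of reads over tens of millions of windows -- the typical window
  holds well under one read).  The generator scatters methylated loci of
  DMR-like size through the CpG deserts; inside a locus the window mean is
  proportional to its CpG count with ``background_mean_count`` the mean at
  average desert CpG density, outside it is
  ``background_mean_count * background_floor``, and CpG islands are
  unmethylated (scaled by ``island_methylation``).  True DMRs occupy a
  subset of the methylated loci.
* ``"flat"``: every window has mean ``background_mean_count``; used for
  statistical-calibration runs where uniform means are wanted.

Windows inside a true DMR have the disease-group mean multiplied (or
divided, per direction) by the fold change, for exactly those samples
carrying the DMR's disease label.  Per-sample library sizes are log-normal
around ``mean_library_size`` and scale every window mean, mimicking
sequencing-depth variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import WindowCountMatrix, make_windows
from .pathology import AnimalRecord, ObserverScore

__all__ = [
    "SimConfig",
    "SimTruth",
    "TrueDmr",
    "Genome",
    "CohortSim",
    "generate_genome",
    "generate_gene_annotation",
    "generate_truth",
    "simulate_counts",
    "simulate_pathology_cohort",
    "write_fasta",
    "write_truth_bed",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: Disease frequencies of the transgenerational F3 vinclozolin male cohort.
DEFAULT_MARGINALS = {
    "testis": 13 / 27,
    "prostate": 13 / 27,
    "kidney": 13 / 26,
    "tumor": 1 / 46,
    "lean": 3 / 27,
    "obese": 7 / 27,
    "late_puberty": 1 / 44,
    "early_puberty": 0 / 44,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 1_000_000
    window_bp: int = 100
    n_disease: int = 6
    n_nondisease: int = 6
    mean_library_size: float = 1_000_000.0
    library_size_cv: float = 0.2
    background_mean_count: float = 50.0
    dispersion: float = 0.1
    n_true_dmrs: int = 30
    dmr_length_bp_range: tuple[int, int] = (500, 1000)
    dmr_fold_change: float = 4.0
    desert_cpg_per_100bp: float = 1.5
    island_cpg_per_100bp: float = 10.0
    island_fraction: float = 0.1
    island_length_bp: int = 1000
    island_methylation: float = 0.05
    coverage_model: str = "cpg"  # "cpg" | "flat"
    n_methylated_loci: int = 150  # total enriched loci, incl. true DMRs
    background_floor: float = 0.005  # nonspecific coverage, fraction of mean
    n_genes: int = 20
    disease_marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    comorbidity_odds: float = 3.0
    n_animals: int = 46
    n_controls: int = 20
    observer_lambda_control: float = 0.5
    observer_shift: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ConfigError("island_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if not 0.0 <= self.library_size_cv < 1.0:
            raise ConfigError("library_size_cv must lie in [0, 1)")
        if self.chrom_length_bp % self.window_bp != 0:
            raise ConfigError("window_bp must divide chrom_length_bp")
        if self.chrom_length_bp < 10 * self.window_bp:
            raise ConfigError("chrom_length_bp must be >= 10 * window_bp")
        lo, hi = self.dmr_length_bp_range
        if not (0 < lo <= hi <= self.chrom_length_bp):
            raise ConfigError("dmr_length_bp_range must fit inside a chromosome")
        if self.dmr_fold_change < 1.0:
            raise ConfigError("dmr_fold_change must be >= 1")
        for name, p in self.disease_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"marginal for {name!r} outside [0, 1]")
        if self.comorbidity_odds < 1.0:
            raise ConfigError("comorbidity_odds must be >= 1")
        if self.coverage_model not in ("cpg", "flat"):
            raise ConfigError("coverage_model must be 'cpg' or 'flat'")
        if self.n_methylated_loci < self.n_true_dmrs:
            raise ConfigError("n_methylated_loci must cover all true DMRs")

    def to_json(self) -> str:
        d = asdict(self)
        d["disease_marginals"] = dict(self.disease_marginals)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class TrueDmr:
    chrom: str
    start: int
    end: int
    fold_change: float
    direction: str  # "up" | "down"
    disease: str = "disease"


@dataclass
class SimTruth:
    true_dmrs: list[TrueDmr]
    disease_labels: dict[str, dict[str, bool]]
    library_sizes: dict[str, int]
    #: methylated loci with no disease effect (high-coverage null regions)
    null_loci: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_dmrs": [asdict(d) for d in self.true_dmrs],
                "disease_labels": self.disease_labels,
                "library_sizes": self.library_sizes,
                "null_loci": self.null_loci,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class Genome:
    sequences: dict[str, str]
    cpg_positions: dict[str, np.ndarray]
    island_intervals: dict[str, list[tuple[int, int]]]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


_NON_CG = np.array(list("ACGT"))


def _random_sequence_without_cg(rng: np.random.Generator, length: int) -> np.ndarray:
    seq = rng.choice(_NON_CG, size=length)
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    seq[cg + 1] = "T"  # destroying the G cannot create a new CG
    return seq


def _island_layout(config: SimConfig) -> list[tuple[int, int]]:
    if config.island_fraction == 0.0:
        return []
    period = int(config.island_length_bp / config.island_fraction)
    out = []
    pos = period // 2
    while pos + config.island_length_bp < config.chrom_length_bp:
        out.append((pos, pos + config.island_length_bp))
        pos += period
    return out


def generate_genome(config: SimConfig) -> Genome:
    """Emit chromosomes with Poisson-placed CpG dinucleotides.

    Deserts carry ``desert_cpg_per_100bp`` CG dimers per 100 bp on
    average; optional islands carry ``island_cpg_per_100bp``.  The base
    sequence is free of accidental CG dimers, so the realized CG count is
    exactly the number of placed CpGs.
    """
    sequences: dict[str, str] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    layout = _island_layout(config)
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        rng = _rng(config, 100 + c)
        L = config.chrom_length_bp
        seq = _random_sequence_without_cg(rng, L)
        in_island = np.zeros(L, dtype=bool)
        for s, e in layout:
            in_island[s:e] = True
        rate = np.where(
            in_island, config.island_cpg_per_100bp, config.desert_cpg_per_100bp
        ) / 100.0
        # Bernoulli field at the local rate; spacing >= 2 avoids overlap
        draws = rng.random(L - 1) < rate[:-1]
        pos = np.flatnonzero(draws)
        if len(pos) > 1:
            keep = np.concatenate([[True], np.diff(pos) >= 2])
            pos = pos[keep]
        seq[pos] = "C"
        seq[pos + 1] = "G"
        sequences[chrom] = "".join(seq)
        arr = np.frombuffer(sequences[chrom].encode(), dtype="S1")
        cpg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        cpg_positions[chrom] = cpg
        islands[chrom] = list(layout)
    return Genome(sequences, cpg_positions, islands)


def generate_truth(
    config: SimConfig,
    genome: Genome,
    diseases: Sequence[str] = ("disease",),
    min_separation_bp: int = 5000,
) -> SimTruth:
    """Place methylated loci in deserts; the first ones carry DMR effects.

    Locus lengths are whole multiples of the window width drawn from
    ``dmr_length_bp_range``; intervals are non-overlapping, avoid islands,
    and keep ``min_separation_bp`` apart so neighbouring loci stay
    distinct after edge extension.  ``n_true_dmrs`` of the
    ``n_methylated_loci`` loci become true DMRs (round-robin over the
    disease names when several are given, so each disease gets a disjoint
    signature); the rest are equally covered in both groups and exercise
    the null.  Disease labels split the first ``n_disease`` samples as
    affected per disease; library sizes are log-normal around the
    configured mean.
    """
    rng = _rng(config, 200)
    w = config.window_bp
    lo = max(1, config.dmr_length_bp_range[0] // w)
    hi = max(lo, config.dmr_length_bp_range[1] // w)
    chroms = sorted(genome.sequences)
    loci: list[tuple[str, int, int]] = []
    # (start, end, required margin): loci keep min_separation_bp apart so
    # edge extension cannot fuse neighbours; islands get 2x the gap
    # distance so island coverage never reaches a locus boundary.
    occupied: dict[str, list[tuple[int, int, int]]] = {
        c: [(s, e, 2000) for s, e in genome.island_intervals[c]] for c in chroms
    }
    n_total = config.n_methylated_loci
    attempts = 0
    while len(loci) < n_total and attempts < 200 * n_total:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        n_win = int(rng.integers(lo, hi + 1))
        length = n_win * w
        max_start_win = (len(genome.sequences[chrom]) - length) // w
        start = int(rng.integers(0, max_start_win + 1)) * w
        end = start + length
        clash = any(
            not (end + margin <= s or e + margin <= start)
            for s, e, margin in occupied[chrom]
        )
        if clash:
            continue
        loci.append((chrom, start, end))
        occupied[chrom].append((start, end, min_separation_bp))
    if len(loci) < n_total:
        raise ConfigError("could not place all methylated loci; genome too small")
    placed = [
        TrueDmr(
            chrom,
            start,
            end,
            config.dmr_fold_change,
            "up" if rng.random() < 0.5 else "down",
            diseases[i % len(diseases)],
        )
        for i, (chrom, start, end) in enumerate(loci[: config.n_true_dmrs])
    ]
    null_loci = sorted(loci[config.n_true_dmrs :])
    placed.sort(key=lambda d: (d.chrom, d.start))

    sample_ids = [f"D{i + 1:02d}" for i in range(config.n_disease)] + [
        f"N{i + 1:02d}" for i in range(config.n_nondisease)
    ]
    labels = {
        s: {d: s.startswith("D") for d in diseases} for s in sample_ids
    }
    sigma2 = np.log1p(config.library_size_cv**2)
    mu = np.log(config.mean_library_size) - sigma2 / 2.0
    libs = np.exp(rng.normal(mu, np.sqrt(sigma2), size=len(sample_ids)))
    library_sizes = {s: int(round(l)) for s, l in zip(sample_ids, libs)}
    return SimTruth(placed, labels, library_sizes, null_loci=null_loci)


def _window_base_means(
    config: SimConfig, genome: Genome | None, truth: SimTruth, grid
) -> np.ndarray:
    if config.coverage_model == "flat" or genome is None:
        return np.full(grid.n_windows, config.background_mean_count)
    mean_cpg_per_window = config.desert_cpg_per_100bp * config.window_bp / 100.0
    per_cpg = config.background_mean_count / mean_cpg_per_window
    floor = config.background_mean_count * config.background_floor
    mu = np.full(grid.n_windows, floor)
    offsets = {c: grid.chrom_offset(c) for c in genome.sequences}
    cpg_per_window: dict[str, np.ndarray] = {}
    for chrom in sorted(genome.sequences):
        n_win = -(-len(genome.sequences[chrom]) // config.window_bp)
        cpg_per_window[chrom] = np.bincount(
            genome.cpg_positions[chrom] // config.window_bp, minlength=n_win
        )[:n_win].astype(float)
    loci = [(d.chrom, d.start, d.end) for d in truth.true_dmrs] + list(truth.null_loci)
    for chrom, start, end in loci:
        i0 = start // config.window_bp
        i1 = end // config.window_bp
        off = offsets[chrom]
        mu[off + i0 : off + i1] = cpg_per_window[chrom][i0:i1] * per_cpg
    for chrom in sorted(genome.sequences):
        off = offsets[chrom]
        for s, e in genome.island_intervals[chrom]:
            i0, i1 = s // config.window_bp, -(-e // config.window_bp)
            mu[off + i0 : off + i1] = (
                cpg_per_window[chrom][i0:i1] * per_cpg * config.island_methylation
            )
    return mu


def simulate_counts(
    config: SimConfig, truth: SimTruth, genome: Genome | None = None
) -> WindowCountMatrix:
    """Draw the window x sample NB count matrix with embedded DMR effects."""
    if config.dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    if genome is not None:
        lengths = genome.chrom_lengths()
    else:
        lengths = {f"chr{c + 1}": config.chrom_length_bp for c in range(config.n_chrom)}
    grid = make_windows(lengths, config.window_bp)
    for d in truth.true_dmrs:
        if d.chrom not in lengths or d.end > lengths[d.chrom]:
            raise ConfigError(f"true DMR {d} outside genome")
    base = _window_base_means(config, genome, truth, grid)
    sample_ids = list(truth.disease_labels)
    rng = _rng(config, 300)
    counts = np.zeros((grid.n_windows, len(sample_ids)), dtype=np.int64)
    offsets = {c: grid.chrom_offset(c) for c in lengths}
    for j, s in enumerate(sample_ids):
        scale = truth.library_sizes[s] / config.mean_library_size
        mu = base * scale
        for d in truth.true_dmrs:
            if truth.disease_labels[s].get(d.disease, False):
                i0 = offsets[d.chrom] + d.start // config.window_bp
                i1 = offsets[d.chrom] + d.end // config.window_bp
                if d.direction == "up":
                    mu[i0:i1] = mu[i0:i1] * d.fold_change
                else:
                    mu[i0:i1] = mu[i0:i1] / d.fold_change
        if config.dispersion == 0.0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
    return WindowCountMatrix(grid, counts, sample_ids, dict(truth.library_sizes))


# ---------------------------------------------------------------------------
# Pathology cohort


@dataclass
class CohortSim:
    records: list[AnimalRecord]
    observer_scores: list[ObserverScore]
    control_records: list[AnimalRecord]
    control_observer_scores: list[ObserverScore]
    true_labels: dict[str, dict[str, bool]]


_SCORED_TISSUES = ("testis", "prostate", "kidney_m")


def simulate_pathology_cohort(config: SimConfig) -> CohortSim:
    """Simulate an exposed cohort plus healthy controls.

    Disease labels follow the configured marginals exactly (Gaussian
    copula with equicorrelation rho = 1 - 1/comorbidity_odds, so odds > 1
    concentrates disease in fewer animals without moving the marginals).
    Observer abnormality counts are Poisson(lambda_control) for healthy
    tissue and Poisson(lambda_control + shift) for diseased tissue, per
    observer, making the mean + 2 SD consensus rule sensitive but
    imperfect.
    """
    diseases = list(config.disease_marginals)
    unknown = set(diseases) - set(DEFAULT_MARGINALS)
    if unknown:
        raise ConfigError(f"unknown disease names: {sorted(unknown)}")
    rng = _rng(config, 400)
    rho = max(0.0, 1.0 - 1.0 / config.comorbidity_odds)
    from scipy.stats import norm

    records: list[AnimalRecord] = []
    scores: list[ObserverScore] = []
    true_labels: dict[str, dict[str, bool]] = {}
    for i in range(config.n_animals):
        aid = f"A{i + 1:03d}"
        z = rng.normal()
        flags: dict[str, bool] = {}
        for d in diseases:
            u = norm.cdf(np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal())
            flags[d] = bool(u < config.disease_marginals[d])
        true_labels[aid] = dict(flags)
        records.append(
            AnimalRecord(animal_id=aid, disease_flags={k: bool(v) for k, v in flags.items()}, lineage="exposed")
        )
        for tissue, dname in zip(_SCORED_TISSUES, ("testis", "prostate", "kidney")):
            lam = config.observer_lambda_control + (
                config.observer_shift if flags.get(dname, False) else 0.0
            )
            for obs in (1, 2, 3):
                scores.append(
                    ObserverScore(aid, tissue, obs, int(rng.poisson(lam)))
                )
    control_records: list[AnimalRecord] = []
    control_scores: list[ObserverScore] = []
    for i in range(config.n_controls):
        aid = f"C{i + 1:03d}"
        control_records.append(
            AnimalRecord(
                animal_id=aid,
                disease_flags={d: False for d in diseases},
                lineage="control",
            )
        )
        for tissue in _SCORED_TISSUES:
            for obs in (1, 2, 3):
                control_scores.append(
                    ObserverScore(
                        aid, tissue, obs, int(rng.poisson(config.observer_lambda_control))
                    )
                )
    return CohortSim(records, scores, control_records, control_scores, true_labels)


# ---------------------------------------------------------------------------
# Gene annotation


def generate_gene_annotation(
    config: SimConfig,
    genome: Genome,
    truth: SimTruth | None = None,
) -> pd.DataFrame:
    """Non-overlapping named gene intervals (BED6-style frame).

    When a truth is given, every other true DMR gets a gene placed 5 kb
    downstream (associated by the 10 kb rule by construction) and the
    remaining genes are kept at least 20 kb from every true DMR (never
    associated), so the association rule is exercised in both directions.
    """
    gene_len = 2000
    rows: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
    dmrs = list(truth.true_dmrs) if truth is not None else []
    for c in genome.sequences:
        occupied[c].extend((d.start, d.end) for d in dmrs if d.chrom == c)

    def free(chrom: str, s: int, e: int, margin: int = 0) -> bool:
        if s < 0 or e > len(genome.sequences[chrom]):
            return False
        return all(e + margin <= os or oe + margin <= s for os, oe in occupied[chrom])

    gi = 1
    for k, d in enumerate(dmrs):
        if gi > config.n_genes:
            break
        if k % 2 == 0:
            s = d.end + 5000
            if free(d.chrom, s, s + gene_len):
                rows.append(
                    {"chrom": d.chrom, "start": s, "end": s + gene_len, "name": f"gene{gi:03d}"}
                )
                occupied[d.chrom].append((s, s + gene_len))
                gi += 1
    rng = _rng(config, 500)
    chroms = sorted(genome.sequences)
    attempts = 0
    while gi <= config.n_genes and attempts < 1000 * config.n_genes:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, len(genome.sequences[chrom]) - gene_len))
        if free(chrom, s, s + gene_len, margin=20_000):
            rows.append(
                {"chrom": chrom, "start": s, "end": s + gene_len, "name": f"gene{gi:03d}"}
            )
            occupied[chrom].append((s, s + gene_len))
            gi += 1
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    df["score"] = 0
    df["strand"] = "+"
    return df


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genome: Genome, path_or_handle, line_width: int = 70) -> None:
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    finally:
        if own:
            fh.close()


def write_truth_bed(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(truth.true_dmrs, 1):
            strand = "+" if d.direction == "up" else "-"
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\ttrue_dmr_{i}_{d.disease}\t0\t{strand}\n"
            )
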