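import numpy as np
import pytest

from epimark.coverage import WindowCountMatrix, make_windows
from epimark.differential import GroupDesign
from epimark.synthetic import Genome, SimConfig, SimTruth, generate_truth, simulate_counts


def flat_truth(config: SimConfig) -> SimTruth:
    """Truth for a flat-coverage sim (no genome needed)."""
    fake = Genome(
        sequences={f"chr{c + 1}": "A" * config.chrom_length_bp for c in range(config.n_chrom)},
        cpg_positions={f"chr{c + 1}": np.array([], dtype=int) for c in range(config.n_chrom)},
        island_intervals={f"chr{c + 1}": [] for c in range(config.n_chrom)},
    )
    return generate_truth(config, fake)


@pytest.fixture(scope="session")
def null_matrix_and_design():
    """2000 flat windows, 6 vs 6, NB dispersion 0.1, no signal."""
    cfg = SimConfig(
        seed=11,
        n_chrom=1,
        chrom_length_bp=200_000,
        coverage_model="flat",
        n_true_dmrs=0,
        n_methylated_loci=0,
        dispersion=0.1,
    )
    truth = flat_truth(cfg)
    matrix = simulate_counts(cfg, truth)
    design = GroupDesign.from_labels({s: s.startswith("D") for s in matrix.sample_ids})
    return matrix, design


@pytest.fixture(scope="session")
def small_grid():
    return make_windows({"chr1": 1000}, 100)


def toy_matrix(counts, library_sizes=None, window_bp=100):
    counts = np.asarray(counts)
    grid = make_windows({"chr1": counts.shape[0] * window_bp}, window_bp)
    sample_ids = [f"s{j}" for j in range(counts.shape[1])]
    if library_sizes is None:
        library_sizes = {s: int(counts[:, j].sum()) for j, s in enumerate(sample_ids)}
    return WindowCountMatrix(grid, counts, sample_ids, library_sizes)
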