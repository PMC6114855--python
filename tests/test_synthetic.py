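"""Generator fidelity: genome CpG structure, NB counts, cohort labels."""

import io

import numpy as np
import pytest

from epimark.pathology import classify_tissue, observer_threshold, summarize_cohort
from epimark.signature import associate_genes
from epimark.synthetic import (
    ConfigError,
    SimConfig,
    generate_gene_annotation,
    generate_genome,
    generate_truth,
    simulate_counts,
    simulate_pathology_cohort,
    write_fasta,
)
from epimark.dmr import DMR
from tests.conftest import flat_truth


def desert_cpg_density(genome, config):
    """CG dimers per 100 bp outside islands, averaged over all chromosomes."""
    total_cpg = 0
    total_bp = 0
    for chrom, seq in genome.sequences.items():
        mask = np.ones(len(seq), dtype=bool)
        for s, e in genome.island_intervals[chrom]:
            mask[max(0, s - 1) : e + 1] = False
        pos = genome.cpg_positions[chrom]
        total_cpg += int(mask[pos].sum())
        total_bp += int(mask.sum())
    return 100.0 * total_cpg / total_bp


class TestGenerateGenome:
    def test_desert_density_within_20pct(self):
        cfg = SimConfig(seed=3, n_chrom=1)
        g = generate_genome(cfg)
        d = desert_cpg_density(g, cfg)
        assert 1.2 <= d <= 1.8

    def test_no_islands_when_fraction_zero(self):
        cfg = SimConfig(seed=3, n_chrom=1, island_fraction=0.0)
        g = generate_genome(cfg)
        assert g.island_intervals["chr1"] == []
        assert 1.2 <= desert_cpg_density(g, cfg) <= 1.8

    def test_islands_are_denser(self):
        cfg = SimConfig(seed=4, n_chrom=1)
        g = generate_genome(cfg)
        island_bp = sum(e - s for s, e in g.island_intervals["chr1"])
        pos = g.cpg_positions["chr1"]
        in_island = np.zeros(len(g.sequences["chr1"]), dtype=bool)
        for s, e in g.island_intervals["chr1"]:
            in_island[s:e] = True
        island_density = 100.0 * in_island[pos].sum() / island_bp
        assert island_density > 3 * cfg.desert_cpg_per_100bp

    def test_alphabet(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length_bp=10_000)
        g = generate_genome(cfg)
        assert set(g.sequences["chr1"]) <= set("ACGT")

    def test_same_seed_byte_identical_fasta(self):
        cfg = SimConfig(seed=6, n_chrom=1, chrom_length_bp=50_000)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_fasta(generate_genome(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(island_fraction=1.5)
        with pytest.raises(ConfigError):
            SimConfig(dispersion=-0.1)
        with pytest.raises(ConfigError):
            SimConfig(chrom_length_bp=1_000_050)  # not a window multiple
        with pytest.raises(ConfigError):
            SimConfig(disease_marginals={"testis": 1.2})
        with pytest.raises(ConfigError):
            SimConfig(library_size_cv=1.0)


class TestGenerateTruth:
    def test_dmrs_snap_to_grid_and_do_not_overlap(self):
        cfg = SimConfig(seed=7)
        g = generate_genome(cfg)
        truth = generate_truth(cfg, g)
        assert len(truth.true_dmrs) == cfg.n_true_dmrs
        for d in truth.true_dmrs:
            assert d.start % cfg.window_bp == 0 and d.end % cfg.window_bp == 0
            assert cfg.dmr_length_bp_range[0] <= d.end - d.start <= cfg.dmr_length_bp_range[1]
        by_chrom = {}
        for d in truth.true_dmrs:
            by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_every_sample_labelled(self):
        cfg = SimConfig(seed=7)
        truth = generate_truth(cfg, generate_genome(cfg))
        assert len(truth.disease_labels) == cfg.n_disease + cfg.n_nondisease
        assert sum(v["disease"] for v in truth.disease_labels.values()) == cfg.n_disease

    def test_multi_disease_signatures_disjoint(self):
        cfg = SimConfig(seed=8, n_true_dmrs=12)
        truth = generate_truth(cfg, generate_genome(cfg), diseases=("testis", "prostate", "kidney"))
        assert {d.disease for d in truth.true_dmrs} == {"testis", "prostate", "kidney"}


class TestSimulateCounts:
    def test_embedded_fold_change_recovered(self):
        cfg = SimConfig(
            seed=9,
            n_chrom=1,
            chrom_length_bp=200_000,
            coverage_model="flat",
            n_true_dmrs=8,
            n_methylated_loci=8,
            library_size_cv=0.0,
        )
        truth = flat_truth(cfg)
        m = simulate_counts(cfg, truth)
        dis = [j for j, s in enumerate(m.sample_ids) if truth.disease_labels[s]["disease"]]
        non = [j for j, s in enumerate(m.sample_ids) if not truth.disease_labels[s]["disease"]]
        ratios = []
        for d in truth.true_dmrs:
            i0 = d.start // cfg.window_bp
            i1 = d.end // cfg.window_bp
            r = m.counts[i0:i1, dis].mean() / m.counts[i0:i1, non].mean()
            ratios.append(r if d.direction == "up" else 1.0 / r)
        assert 3.0 <= float(np.mean(ratios)) <= 5.0

    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimConfig(
            seed=10,
            n_chrom=1,
            chrom_length_bp=300_000,
            coverage_model="flat",
            n_true_dmrs=0,
            n_methylated_loci=0,
            dispersion=0.0,
            library_size_cv=0.0,
        )
        m = simulate_counts(cfg, flat_truth(cfg))
        col = m.counts[:, 0].astype(float)
        assert col.var() == pytest.approx(col.mean(), rel=0.1)

    def test_nb_moments_match_parameterization(self):
        # Var = mu + phi * mu^2 across >=1000 windows of constant mean
        phi, mu0 = 0.2, 50.0
        cfg = SimConfig(
            seed=12,
            n_chrom=1,
            chrom_length_bp=300_000,
            coverage_model="flat",
            n_true_dmrs=0,
            n_methylated_loci=0,
            dispersion=phi,
            background_mean_count=mu0,
            library_size_cv=0.0,
        )
        m = simulate_counts(cfg, flat_truth(cfg))
        col = m.counts[:, 0].astype(float)
        expected_var = col.mean() + phi * col.mean() ** 2
        assert col.var() == pytest.approx(expected_var, rel=0.15)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=14, n_chrom=1, chrom_length_bp=100_000, coverage_model="flat",
                        n_true_dmrs=0, n_methylated_loci=0)
        t = flat_truth(cfg)
        m1 = simulate_counts(cfg, t)
        m2 = simulate_counts(cfg, t)
        assert np.array_equal(m1.counts, m2.counts)

    def test_negative_dispersion_rejected_at_config(self):
        with pytest.raises(ConfigError):
            SimConfig(dispersion=-1.0)


class TestCohort:
    def test_marginals_within_sampling_error(self):
        cfg = SimConfig(seed=15, n_animals=500)
        sim = simulate_pathology_cohort(cfg)
        summ = summarize_cohort(sim.records)
        for d, p in cfg.disease_marginals.items():
            se = np.sqrt(max(p * (1 - p), 1e-4) / cfg.n_animals)
            assert abs(summ.frequency[d] - p) <= 4 * se + 0.01

    def test_comorbidity_overdisperses_disease_counts(self):
        # positive dependence with fixed marginals concentrates disease:
        # the per-animal disease-count variance exceeds the independence
        # (Poisson-binomial) variance and healthy animals become commoner
        cfg = SimConfig(seed=16, n_animals=500, comorbidity_odds=3.0)
        sim = simulate_pathology_cohort(cfg)
        counts = np.array([sum(lbl.values()) for lbl in sim.true_labels.values()])
        probs = np.array(list(cfg.disease_marginals.values()))
        indep_var = float((probs * (1 - probs)).sum())
        assert counts.var() > indep_var * 1.3
        dp = np.zeros(len(probs) + 1)
        dp[0] = 1.0
        for p in probs:
            dp[1:] = dp[1:] * (1 - p) + dp[:-1] * p
            dp[0] *= 1 - p
        assert (counts == 0).mean() > dp[0] + 0.03

    def test_zero_marginals_zero_disease(self):
        cfg = SimConfig(seed=17, disease_marginals={k: 0.0 for k in ("testis", "kidney")})
        sim = simulate_pathology_cohort(cfg)
        assert summarize_cohort(sim.records, diseases=("testis", "kidney")).affected == {
            "testis": 0,
            "kidney": 0,
        }

    def test_fixed_seed_identical_cohort(self):
        cfg = SimConfig(seed=18)
        a = simulate_pathology_cohort(cfg)
        b = simulate_pathology_cohort(cfg)
        assert a.true_labels == b.true_labels
        assert [s.abnormality_count for s in a.observer_scores] == [
            s.abnormality_count for s in b.observer_scores
        ]

    def _recovery(self, cfg):
        sim = simulate_pathology_cohort(cfg)
        cutoffs = observer_threshold(sim.control_observer_scores)
        tp = fp = fn = tn = 0
        by_animal = {}
        for s in sim.observer_scores:
            by_animal.setdefault((s.animal_id, s.tissue), []).append(s)
        for (aid, tissue), scores in by_animal.items():
            if tissue != "testis":
                continue
            call = classify_tissue(scores, cutoffs)
            true = sim.true_labels[aid]["testis"]
            tp += call and true
            fp += call and not true
            fn += (not call) and true
            tn += (not call) and not true
        return tp / (tp + fn), tn / (tn + fp)

    def test_classification_recovers_true_labels_and_improves_with_shift(self):
        sens_lo, spec_lo = self._recovery(SimConfig(seed=19, n_animals=200, observer_shift=1.0))
        sens_hi, spec_hi = self._recovery(SimConfig(seed=19, n_animals=200, observer_shift=4.0))
        assert sens_hi >= 0.85 and spec_hi >= 0.9
        assert sens_hi > sens_lo

    def test_unknown_disease_name_rejected(self):
        with pytest.raises(ConfigError):
            simulate_pathology_cohort(SimConfig(disease_marginals={"gout": 0.1}))


class TestGeneAnnotation:
    def test_disjoint_and_in_bounds(self):
        cfg = SimConfig(seed=20)
        g = generate_genome(cfg)
        truth = generate_truth(cfg, g)
        genes = generate_gene_annotation(cfg, g, truth)
        assert len(genes) == cfg.n_genes
        for chrom, sub in genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= len(g.sequences[chrom])).all()
            assert all(a <= b for a, b in zip(sub["end"][:-1], sub["start"][1:]))

    def test_association_rule_exercised_both_ways(self):
        cfg = SimConfig(seed=21)
        g = generate_genome(cfg)
        truth = generate_truth(cfg, g)
        genes = generate_gene_annotation(cfg, g, truth)
        dmr_objs = [
            DMR(f"{d.chrom}:{i}", d.chrom, d.start, d.end, 1, 1e-6)
            for i, d in enumerate(truth.true_dmrs)
        ]
        assoc = associate_genes(dmr_objs, genes)
        n_with = sum(1 for v in assoc.values() if v)
        assert 0 < n_with < len(assoc)  # some associated, some not, by construction
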