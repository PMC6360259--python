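import numpy as np
import pandas as pd
import pytest

from pgcna import (
    SimConfig,
    adjusted_rand_index,
    planted_signatures,
    simulate_de_benchmark,
    simulate_timecourse,
    spearman_all_pairs,
)
from pgcna.simulate import NULL_MODULE

from oracles import ari_from_contingency


class TestSimulateTimecourse:
    def test_same_seed_bit_identical(self):
        a = simulate_timecourse(SimConfig(seed=3))
        b = simulate_timecourse(SimConfig(seed=3))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.true_partition == b.true_partition
        assert a.signatures.sets == b.signatures.sets

    def test_different_seeds_differ(self):
        a = simulate_timecourse(SimConfig(seed=3))
        b = simulate_timecourse(SimConfig(seed=4))
        assert not a.expression.values.equals(b.expression.values)

    def test_design_dimensions(self, default_dataset):
        ds = default_dataset
        cfg = ds.config
        assert len(ds.expression.sample_ids) == len(cfg.conditions) * len(cfg.timepoints) * cfg.n_donors
        assert len(set(ds.annotation.values())) == cfg.n_genes
        assert len(ds.expression.probe_ids) >= cfg.n_genes
        labels = set(ds.true_partition.values())
        assert labels == {NULL_MODULE} | {f"M{i + 1}" for i in range(cfg.n_modules)}

    def test_null_fraction_and_min_module_size(self, default_dataset):
        ds = default_dataset
        n_null = sum(1 for m in ds.true_partition.values() if m == NULL_MODULE)
        assert n_null == round(ds.config.n_genes * ds.config.null_fraction)
        sizes = pd.Series([m for m in ds.true_partition.values() if m != NULL_MODULE]).value_counts()
        assert sizes.min() >= 4

    def test_noiseless_limit_gives_perfect_within_module_correlation(self):
        cfg = SimConfig(
            seed=5, noise_sd=1e-9, donor_sd=0.0, probe_offset_sd=0.0,
            probe_noise_sd=1e-12, probes_per_gene_mean=1.0,
        )
        ds = simulate_timecourse(cfg)
        genes = ds.expression.values.copy()
        genes.index = [ds.annotation[p] for p in genes.index]
        module = [g for g, m in ds.true_partition.items() if m == "M1"][:5]
        rho = spearman_all_pairs(genes.loc[module])
        off_diag = rho.to_numpy()[~np.eye(len(module), dtype=bool)]
        # donors within a group are exactly tied; the vestigial noise breaks
        # those ties at random, so rho approaches 1 without reaching it
        assert np.abs(off_diag).min() > 0.99

    def test_within_module_correlation_exceeds_between(self):
        """Mean within-module |rho| beats between-module |rho| by >= 0.3
        at default noise (checked over 5 seeds)."""
        gaps = []
        for seed in range(5):
            ds = simulate_timecourse(SimConfig(seed=seed))
            genes = ds.expression.values.copy()
            genes.index = [ds.annotation[p] for p in genes.index]
            genes = genes[~genes.index.duplicated()]
            rho = spearman_all_pairs(genes).abs()
            labels = np.array([ds.true_partition[g] for g in rho.index])
            mask_planted = labels != NULL_MODULE
            sub = rho.to_numpy()[np.ix_(mask_planted, mask_planted)]
            lab = labels[mask_planted]
            same = lab[:, None] == lab[None, :]
            np.fill_diagonal(same, False)
            off = ~same
            np.fill_diagonal(off, False)
            gaps.append(sub[same].mean() - sub[off].mean())
        assert np.median(gaps) >= 0.3

    def test_true_de_sets_respect_threshold(self, default_dataset):
        ds = default_dataset
        for de in ds.true_de:
            base = ds.noiseless[(de.condition, ds.config.timepoints[0])]
            delta = ds.noiseless[(de.condition, de.timepoint)] - base
            for gene in de.genes:
                if de.direction == "induced":
                    assert delta[gene] > ds.config.de_truth_log2fc
                else:
                    assert delta[gene] < -ds.config.de_truth_log2fc

    def test_recovery_degrades_monotonically_with_noise(self):
        """Median pipeline ARI is non-increasing through noise sd
        0.5 → 1.0 → 2.0 → 4.0 (3 seeds, 50-run ensembles)."""
        from pgcna.simulate import recover_modules, score_recovery

        medians = []
        for noise in (0.5, 1.0, 2.0, 4.0):
            aris = []
            for seed in range(3):
                ds = simulate_timecourse(SimConfig(seed=seed, noise_sd=noise))
                part, _, _ = recover_modules(ds, n_runs=50, keep=5, base_seed=42)
                aris.append(score_recovery(ds, part)["ari"])
            medians.append(float(np.median(aris)))
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            simulate_timecourse(SimConfig(n_genes=40, n_modules=9, conditions=["C1"]))


class TestPlantedSignatures:
    def test_counts_and_exact_membership(self, default_dataset):
        sigs = planted_signatures(default_dataset, n_decoys=20)
        assert len(sigs) == default_dataset.config.n_modules + 20
        modules = {}
        for gene, m in default_dataset.true_partition.items():
            if m != NULL_MODULE:
                modules.setdefault(m, set()).add(gene)
        for m, members in modules.items():
            assert sigs[f"SIG_{m}"] == members

    def test_decoys_reproducible(self, default_dataset):
        a = planted_signatures(default_dataset, n_decoys=5)
        b = planted_signatures(default_dataset, n_decoys=5)
        assert a.sets == b.sets


class TestDeBenchmark:
    def test_truth_probes_carry_the_shift(self):
        matrix, truth = simulate_de_benchmark(n_null=50, n_shifted=10, shift=2.0, seed=1)
        a_cols = matrix.group_samples("A", "t0")
        b_cols = matrix.group_samples("B", "t0")
        delta = (matrix.values[b_cols].mean(axis=1) - matrix.values[a_cols].mean(axis=1)).abs()
        assert delta[sorted(truth)].min() > 1.0
        null_probes = [p for p in matrix.probe_ids if p not in truth]
        assert delta[null_probes].median() < 0.5

    def test_reproducible(self):
        m1, t1 = simulate_de_benchmark(seed=9)
        m2, t2 = simulate_de_benchmark(seed=9)
        assert t1 == t2
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        part = {f"g{i}": f"M{i % 3}" for i in range(12)}
        assert adjusted_rand_index(part, dict(part)) == 1.0

    def test_label_permutation_invariant(self):
        a = {f"g{i}": f"M{i % 3}" for i in range(12)}
        swap = {"M0": "M1", "M1": "M2", "M2": "M0"}
        b = {g: swap[m] for g, m in a.items()}
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_matches_contingency_formula_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        a = {g: f"M{rng.integers(0, 4)}" for g in genes}
        b = {g: f"K{rng.integers(0, 3)}" for g in genes}
        expected = ari_from_contingency([a[g] for g in genes], [b[g] for g in genes])
        assert adjusted_rand_index(a, b) == pytest.approx(expected, abs=1e-12)

    def test_two_module_plant_vs_singletons_closed_form(self):
        plant = {f"g{i}": ("M1" if i < 4 else "M2") for i in range(8)}
        singletons = {f"g{i}": f"S{i}" for i in range(8)}
        expected = ari_from_contingency(
            [plant[g] for g in sorted(plant)], [singletons[g] for g in sorted(plant)]
        )
        assert adjusted_rand_index(plant, singletons) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"a": "M1"}, {"b": "M1"})
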