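import itertools

import numpy as np
import pytest

from chromstate.classify import classify_peaks
from chromstate.expression import differential_expression, filter_expressed
from chromstate.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_coverage,
    generate_expression,
    generate_genome,
    generate_peaks,
    largest_remainder_counts,
    write_bundle,
)


def small_config(seed=0, **kwargs):
    kwargs.setdefault("n_genes", 80)
    kwargs.setdefault("n_peaks", 120)
    return SyntheticConfig(seed=seed, **kwargs)


class TestConfig:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(composition={"distal-isolated": 0.5})

    def test_largest_remainder_totals(self, rng):
        for _ in range(50):
            raw = rng.random(5)
            fractions = dict(zip("abcde", raw / raw.sum()))
            total = int(rng.integers(1, 500))
            counts = largest_remainder_counts(fractions, total)
            assert sum(counts.values()) == total
            for k in fractions:
                assert abs(counts[k] - fractions[k] * total) < 1


class TestGenome:
    def test_deterministic_given_seed(self):
        a = generate_genome(small_config(seed=9))
        b = generate_genome(small_config(seed=9))
        assert a == b
        c = generate_genome(small_config(seed=10))
        assert a != c

    def test_single_gene(self):
        genome, tss = generate_genome(small_config(n_genes=1, n_peaks=1))
        assert len(tss) == 1

    def test_tss_pairwise_spacing(self):
        _, tss = generate_genome(small_config(seed=4, n_genes=150))
        for a, b in itertools.combinations(tss, 2):
            if a.chrom == b.chrom:
                assert abs(a.tss - b.tss) >= 5000

    def test_explicit_lengths_checked(self):
        with pytest.raises(ValueError, match="need"):
            generate_genome(small_config(chrom_lengths=[10_000, 10_000]))


class TestPeaks:
    def test_all_isolated_composition(self):
        cfg = small_config(composition={"distal-isolated": 1.0})
        genome, tss = generate_genome(cfg)
        factor, marks, truth = generate_peaks(cfg, tss, genome)
        classified = classify_peaks(
            factor, tss, marks["k4me3"], marks["k4me1"], marks["k27ac"],
            marks["k27me3"])
        assert all(p.category.label == "isolated" for p in classified.peaks)
        assert all(len(m) == 0 for m in marks.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_labels_recovered_every_seed(self, seed):
        cfg = small_config(seed=seed)
        genome, tss = generate_genome(cfg)
        factor, marks, truth = generate_peaks(cfg, tss, genome)
        classified = classify_peaks(
            factor, tss, marks["k4me3"], marks["k4me1"], marks["k27ac"],
            marks["k27me3"])
        assert len(classified) == cfg.n_peaks
        for p in classified.peaks:
            assert truth.peak_category[p.peak.name] == (
                p.category.locality, p.category.label)

    def test_too_many_proximal_peaks_rejected(self):
        cfg = small_config(n_genes=3, n_peaks=120,
                           composition={"proximal-active": 1.0})
        genome, tss = generate_genome(cfg)
        with pytest.raises(ValueError, match="proximal"):
            generate_peaks(cfg, tss, genome)


class TestCoverage:
    def test_noiseless_fixed_spacing_recovered_everywhere(self):
        from chromstate.nucleosome import call_many
        cfg = small_config(
            seed=2, spacing_conditions={"c": (600.0, 1e-9)}, coverage_noise=0.0)
        genome, tss = generate_genome(cfg)
        tracks, truth = generate_coverage(cfg, tss, genome)
        calls, nocalls = call_many(tracks["c"], tss)
        assert not nocalls
        for call in calls:
            assert abs(call.distance - 600) <= 20  # two bin widths

    def test_condition_medians_recovered(self):
        from chromstate.nucleosome import call_many, compare_spacing
        cfg = small_config(seed=3, n_genes=200)
        genome, tss = generate_genome(cfg)
        tracks, truth = generate_coverage(cfg, tss, genome)
        calls = {c: call_many(tracks[c], tss)[0] for c in tracks}
        cmp = compare_spacing(calls["wt"], calls["mut"])
        assert cmp.median_a == pytest.approx(589, abs=15)
        assert cmp.median_b == pytest.approx(482, abs=15)

    def test_truth_spacing_above_floor(self):
        cfg = small_config(seed=5)
        genome, tss = generate_genome(cfg)
        _, truth = generate_coverage(cfg, tss, genome)
        for cond in truth.spacing:
            assert min(truth.spacing[cond].values()) > cfg.spacing_min


class TestExpression:
    def build(self, seed=0, **kwargs):
        cfg = small_config(seed=seed, **kwargs)
        genome, tss = generate_genome(cfg)
        _, _, truth = generate_peaks(cfg, tss, genome)
        matrix, signatures, truth = generate_expression(cfg, tss, truth)
        return cfg, matrix, signatures, truth

    def test_planted_de_recovered_at_low_noise(self):
        cfg, matrix, _, truth = self.build(seed=1, de_noise_sd=0.1,
                                           de_effect_size=2.0)
        de = differential_expression(filter_expressed(matrix), "WT", "KO")
        called_up = {r.gene_id for r in de if r.direction == "up"}
        called_down = {r.gene_id for r in de if r.direction == "down"}
        planted_up = {g for g, d in truth.de_direction.items() if d == "up"}
        planted_down = {g for g, d in truth.de_direction.items() if d == "down"}
        assert called_up == planted_up
        assert called_down == planted_down

    def test_filter_retains_most_genes(self):
        """Baseline N(7, 1.2) against the >= 6 filter: the Normal tail puts
        retention above 80% on average."""
        rates = []
        for seed in range(10):
            _, matrix, _, _ = self.build(seed=seed, n_genes=400)
            kept = filter_expressed(matrix, 6.0)
            rates.append(len(kept.gene_ids) / len(matrix.gene_ids))
        assert np.mean(rates) > 0.8

    def test_signature_blocks_disjoint_from_de(self):
        _, _, signatures, truth = self.build(seed=2)
        sig_genes = {g for members in signatures.values() for g in members}
        assert sig_genes.isdisjoint(truth.de_direction)

    def test_null_type_one_error_calibrated(self):
        """With no planted effects the raw-p positive rate sits at the
        nominal 5% (within 2 points averaged over 20 seeds)."""
        rates = []
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed, n_genes=400, n_peaks=4,
                                  de_up_fraction=0.0, de_down_fraction=0.0,
                                  signature_shifts={})
            genome, tss = generate_genome(cfg)
            matrix, _, _ = generate_expression(cfg, tss, GroundTruth())
            de = differential_expression(matrix, "WT", "KO")
            rates.append(np.mean([r.pvalue <= 0.05 for r in de]))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestBundleDeterminism:
    def test_identical_bytes_across_runs(self, tmp_path):
        cfg = small_config(seed=12, n_genes=120, n_peaks=60)
        write_bundle(cfg, tmp_path / "a")
        write_bundle(cfg, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_stage_streams_independent(self):
        cfg = small_config(seed=8)
        genome, tss = generate_genome(cfg)
        # regenerating coverage alone must not perturb expression output
        m1, _, _ = generate_expression(cfg, tss, GroundTruth())
        generate_coverage(cfg, tss, genome)
        m2, _, _ = generate_expression(cfg, tss, GroundTruth())
        assert np.array_equal(m1.values.to_numpy(), m2.values.to_numpy())
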