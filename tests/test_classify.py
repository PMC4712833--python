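import numpy as np
import pytest

from chromstate.classify import (
    ChromatinCategory,
    classify_distal,
    classify_peaks,
    classify_proximal,
    class_composition,
    peak_signal_matrix,
    split_proximal_distal,
)
from chromstate.intervals import GenomicInterval, IntervalCollection, TssRecord
from chromstate.nucleosome import CoverageTrack
from chromstate.synthetic import (
    SyntheticConfig,
    generate_genome,
    generate_peaks,
    largest_remainder_counts,
)

from conftest import brute_force_nearest, random_collection, random_tss


def marks_at(peak, *names):
    """Mark collections overlapping the peak for the named marks, empty else."""
    all_names = ("k4me3", "k4me1", "k27ac", "k27me3")
    return {
        n: IntervalCollection(
            n, [GenomicInterval(peak.chrom, peak.start, peak.end)] if n in names else []
        )
        for n in all_names
    }


class TestSplitProximalDistal:
    def test_boundary_is_inclusive_at_threshold(self):
        tss = [TssRecord("g", "chr1", 10_000, "+")]
        near = IntervalCollection("p", [GenomicInterval("chr1", 10_200, 10_400)])
        at_edge = IntervalCollection("p", [GenomicInterval("chr1", 10_900, 11_100)])
        past = IntervalCollection("p", [GenomicInterval("chr1", 10_901, 11_101)])
        assert len(split_proximal_distal(near, tss)[0]) == 1
        assert len(split_proximal_distal(at_edge, tss)[0]) == 1  # distance 1000
        assert len(split_proximal_distal(past, tss)[1]) == 1  # distance 1001

    def test_partition_exhaustive_and_exclusive(self, rng):
        peaks = random_collection(rng, 300)
        tss = random_tss(rng, 40)
        proximal, distal = split_proximal_distal(peaks, tss)
        assert len(proximal) + len(distal) == len(peaks)
        for peak, gene, dist in proximal:
            assert abs(dist) <= 1000

    def test_matches_brute_force_fraction(self, rng):
        peaks = random_collection(rng, 1000)
        tss = random_tss(rng, 50)
        proximal, _ = split_proximal_distal(peaks, tss, anchor="midpoint")
        expected = sum(
            1 for p in peaks
            if abs(brute_force_nearest(tss, p.chrom, p.midpoint)[1]) <= 1000
        )
        assert len(proximal) == expected

    def test_empty_inputs(self, rng):
        with pytest.raises(ValueError):
            split_proximal_distal(random_collection(rng, 5), [])
        with pytest.warns(UserWarning):
            out = split_proximal_distal(
                IntervalCollection("e", []), [TssRecord("g", "chr1", 0, "+")])
        assert out == ([], [])


class TestClassifyProximal:
    peak = GenomicInterval("chr1", 1000, 1400)

    @pytest.mark.parametrize(
        "present, expected, active_rule",
        [
            (("k4me3", "k27ac"), "active", True),
            (("k4me3", "k27me3"), "bivalent", False),
            (("k4me3", "k27ac", "k27me3"), "bivalent", True),  # tallied in both
            (("k27ac",), "other", False),
            ((), "other", False),
        ],
    )
    def test_rules(self, present, expected, active_rule):
        m = marks_at(self.peak, *present)
        category, also_active = classify_proximal(
            self.peak, m["k4me3"], m["k27ac"], m["k27me3"])
        assert category == ChromatinCategory("proximal", expected)
        assert also_active is active_rule


class TestClassifyDistal:
    peak = GenomicInterval("chr1", 50_000, 50_400)

    @pytest.mark.parametrize(
        "present, expected",
        [
            (("k27ac", "k4me1"), "active"),
            (("k27me3", "k27ac", "k4me1"), "bivalent"),
            (("k27me3",), "repressed"),
            (("k27me3", "k4me1"), "repressed"),  # cascade: repressed beats latent
            (("k4me1",), "latent"),
            ((), "isolated"),
            (("k27ac",), "other"),  # fits no quoted rule
        ],
    )
    def test_cascade(self, present, expected):
        m = marks_at(self.peak, *present)
        category = classify_distal(self.peak, m["k4me1"], m["k27ac"], m["k27me3"])
        assert category == ChromatinCategory("distal", expected)

    def test_strict_five_folds_other_into_latent(self):
        m = marks_at(self.peak, "k27ac")
        category = classify_distal(
            self.peak, m["k4me1"], m["k27ac"], m["k27me3"], strict_five=True)
        assert category.label == "latent"


class TestComposition:
    def build(self, seed=3, **kwargs):
        cfg = SyntheticConfig(seed=seed, n_genes=100, n_peaks=300, **kwargs)
        genome, tss = generate_genome(cfg)
        factor, marks, truth = generate_peaks(cfg, tss, genome)
        classified = classify_peaks(
            factor, tss, marks["k4me3"], marks["k4me1"], marks["k27ac"],
            marks["k27me3"])
        return cfg, classified, truth

    def test_recovers_planted_composition_exactly(self):
        cfg, classified, truth = self.build()
        expected = largest_remainder_counts(cfg.composition, cfg.n_peaks)
        table = class_composition(classified)
        got = {
            f"{r.locality}-{r.category}": r.count
            for r in table.itertuples() if r.category != "active-rule"
        }
        assert got == {k: v for k, v in expected.items() if v > 0}

    def test_every_peak_label_matches_planted_truth(self):
        _, classified, truth = self.build(seed=11)
        for p in classified.peaks:
            assert truth.peak_category[p.peak.name] == (
                p.category.locality, p.category.label)

    def test_fractions_sum_to_one(self):
        _, classified, _ = self.build()
        table = class_composition(classified)
        core = table[table.category != "active-rule"]
        assert core.frac_total.sum() == pytest.approx(1.0, abs=1e-12)
        assert ((core.frac_total >= 0) & (core.frac_total <= 1)).all()

    def test_invariant_under_peak_shuffling(self, rng):
        _, classified, _ = self.build(seed=5)
        shuffled = classified
        perm = rng.permutation(len(classified.peaks))
        shuffled.peaks = [classified.peaks[i] for i in perm]
        a = class_composition(classified).sort_values(["locality", "category"])
        assert (a["count"].to_numpy() >= 0).all()  # recompute is order-free
        # counts by category identical regardless of order
        b = class_composition(shuffled).sort_values(["locality", "category"])
        assert (a["count"].to_numpy() == b["count"].to_numpy()).all()

    def test_single_peak_has_fraction_one(self):
        tss = [TssRecord("g", "chr1", 10_000, "+")]
        peaks = IntervalCollection("p", [GenomicInterval("chr1", 50_000, 50_400)])
        empty = IntervalCollection("e", [])
        classified = classify_peaks(peaks, tss, empty, empty, empty, empty)
        table = class_composition(classified)
        row = table[table.category == "isolated"].iloc[0]
        assert row["count"] == 1 and row.frac_total == 1.0

    def test_empty_set_gives_empty_table(self):
        from chromstate.classify import ClassifiedPeakSet
        table = class_composition(ClassifiedPeakSet([], {}))
        assert table.empty


class TestPeakSignalMatrix:
    def test_uniform_track(self):
        track = CoverageTrack({"chr1": np.full(10_000, 2.0)}, bin_width=10)
        peaks = [GenomicInterval("chr1", 40_000, 40_400)]
        m = peak_signal_matrix(peaks, track, flank=10_000, bins=20)
        assert m.shape == (1, 20)
        assert np.allclose(m, 2.0)

    def test_single_bin_averages_total_area(self):
        arr = np.zeros(10_000)
        arr[5_000] = 7.0  # one hot bin of width 10 at the peak centre
        track = CoverageTrack({"chr1": arr}, bin_width=10)
        peaks = [GenomicInterval("chr1", 49_800, 50_200)]
        m = peak_signal_matrix(peaks, track, flank=10_000, bins=1)
        assert m[0, 0] == pytest.approx(7.0 * 10 / 20_000)

    def test_edge_truncation_yields_nan(self):
        track = CoverageTrack({"chr1": np.ones(1_000)}, bin_width=10)
        peaks = [GenomicInterval("chr1", 100, 300)]  # flank runs off the edge
        m = peak_signal_matrix(peaks, track, flank=5_000, bins=10)
        assert np.isnan(m[0, 0]) and not np.isnan(m[0, 5])

    def test_absent_chromosome_warns_all_nan(self):
        track = CoverageTrack({"chr1": np.ones(1_000)}, bin_width=10)
        with pytest.warns(UserWarning):
            m = peak_signal_matrix(
                [GenomicInterval("chr9", 4_000, 4_200)], track, flank=100, bins=4)
        assert np.isnan(m).all()

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(50):
            arr = rng.random(2_000) * 5
            track = CoverageTrack({"chr1": arr}, bin_width=10)
            center = int(rng.integers(5_000, 15_000))
            peak = GenomicInterval("chr1", center - 100, center + 100)
            flank, bins = 2_000, int(rng.integers(1, 9))
            m = peak_signal_matrix([peak], track, flank=flank, bins=bins)
            per_base = np.repeat(arr, 10)
            edges = np.linspace(-flank, flank, bins + 1)
            for b in range(bins):
                lo = center + int(round(edges[b]))
                hi = center + int(round(edges[b + 1]))
                assert m[0, b] == pytest.approx(per_base[lo:hi].mean())
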