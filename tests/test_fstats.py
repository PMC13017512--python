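import numpy as np
import pytest

from admixkit import fstats, genodata, synthgen
from admixkit.errors import EstimationError
from admixkit.synthgen import AdmixtureEvent, AdmixtureGraph, DriftEdge, SampleSpec

from _oracles import abba_baba_d, brute_d, brute_f4


def _panel_from_freqs(freqs, specs, seed):
    rng = np.random.default_rng(seed)
    return synthgen.sample_panel(freqs, specs, rng)


def _complete_specs(pops, n=3):
    return [SampleSpec(p, n=n, ploidy=1, mean_depth=None) for p in pops]


class TestMakeBlocks:
    def test_span_floor_arithmetic(self):
        sites = genodata.make_sites(
            ["1"] * 3, [1, 4_999_999, 5_000_001], ["A"] * 3, ["C"] * 3
        )
        spec = fstats.make_blocks(sites, "span", 5_000_000)
        assert spec.block_ids.tolist() == [0, 0, 1]

    def test_count_mode_sizes(self):
        sites = genodata.make_sites(
            ["1"] * 250, np.arange(1, 251) * 10, ["A"] * 250, ["C"] * 250
        )
        spec = fstats.make_blocks(sites, "count", 100)
        sizes = np.bincount(spec.block_ids)
        assert sizes.tolist() == [100, 100, 50]

    def test_span_never_joins_chromosomes(self):
        sites = genodata.make_sites(
            ["1", "1", "2", "2"], [10, 20, 10, 20], ["A"] * 4, ["C"] * 4
        )
        spec = fstats.make_blocks(sites, "span", 5_000_000)
        assert spec.block_ids.tolist() == [0, 0, 1, 1]

    def test_empty_sites(self):
        sites = genodata.make_sites([], [], [], [])
        assert fstats.make_blocks(sites, "span", 100).n_blocks == 0


@pytest.fixture(scope="module")
def four_pop_panel():
    """Complete-data panel over a 4-leaf tree plus outgroup."""
    graph = AdmixtureGraph(
        [
            DriftEdge("root", "O", 0.08),
            DriftEdge("root", "anc", 0.03),
            DriftEdge("anc", "ab", 0.04),
            DriftEdge("ab", "A", 0.03),
            DriftEdge("ab", "B", 0.03),
            DriftEdge("anc", "cd", 0.04),
            DriftEdge("cd", "C", 0.03),
            DriftEdge("cd", "D", 0.03),
        ]
    )
    rng = np.random.default_rng(11)
    freqs = synthgen.simulate_frequencies(graph, 4000, rng)
    panel = synthgen.sample_panel(freqs, _complete_specs(["O", "A", "B", "C", "D"]), rng)
    blocks = fstats.make_blocks(panel.sites, "count", 100)
    return panel, blocks


class TestF3:
    def test_symmetric_in_first_two_arguments(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r1 = fstats.f3(panel, "A", "B", "O", blocks)
        r2 = fstats.f3(panel, "B", "A", "O", blocks)
        assert r1.estimate == r2.estimate
        assert r1.jackknife_se == r2.jackknife_se

    def test_identical_populations_give_zero_with_degenerate_flag(self):
        sites = genodata.make_sites(["1"] * 4, [10, 20, 30, 40], ["A"] * 4, ["C"] * 4)
        samples = genodata.make_samples(
            ["a", "b", "c"], ["A", "B", "C"], ploidy=1
        )
        calls = np.tile(np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0]]), 1).astype(np.int8)
        panel = genodata.GenotypePanel(sites, samples, calls)
        blocks = fstats.make_blocks(panel.sites, "count", 2)
        r = fstats.f3(panel, "A", "B", "C", blocks)
        assert r.estimate == 0.0
        assert r.degenerate and r.z_score == 0.0

    def test_star_tree_estimates_shared_drift(self, star_graph):
        """Outgroup-f3 of two sisters recovers the shared post-split drift
        predicted by the closed-form moment oracle (up to the finite-vertex
        sampling bias E[c(1-c)]/n_chrom)."""
        expected = synthgen.expected_f3(star_graph, "A", "B", "O")
        bias = synthgen.expected_heterozygosity(star_graph, "O") / 40
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            freqs = synthgen.simulate_frequencies(star_graph, 20_000, rng)
            panel = synthgen.sample_panel(
                freqs,
                [
                    SampleSpec("O", n=20, ploidy=2, mean_depth=None),
                    SampleSpec("A", n=3, ploidy=1, mean_depth=None),
                    SampleSpec("B", n=3, ploidy=1, mean_depth=None),
                ],
                rng,
            )
            blocks = fstats.make_blocks(panel.sites, "count", 100)
            ests.append(fstats.f3(panel, "A", "B", "O", blocks).estimate)
        assert abs(np.mean(ests) - (expected + bias)) < 0.002
        assert np.mean(ests) == pytest.approx(expected, rel=0.25)

    def test_zero_usable_sites_raises(self, tiny_panel):
        blocks = fstats.make_blocks(tiny_panel.sites, "count", 2)
        empty = tiny_panel.take_sites(np.zeros(4, dtype=bool))
        blocks0 = fstats.make_blocks(empty.sites, "count", 2)
        with pytest.raises(EstimationError):
            fstats.f3(empty, "P1", "P2", "P2", blocks0)


class TestF4:
    def test_equal_first_pair_is_exactly_zero(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r = fstats.f4(panel, "A", "A", "C", "D", blocks)
        assert r.estimate == 0.0

    def test_swapping_second_pair_negates(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r1 = fstats.f4(panel, "A", "B", "C", "D", blocks)
        r2 = fstats.f4(panel, "A", "B", "D", "C", blocks)
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)

    def test_additivity_in_third_slot(self, four_pop_panel):
        """f4(A,B;C,D) = f4(A,B;C,E) + f4(A,B;E,D) exactly on complete data."""
        panel, blocks = four_pop_panel
        whole = fstats.f4(panel, "A", "B", "C", "D", blocks).estimate
        part1 = fstats.f4(panel, "A", "B", "C", "O", blocks).estimate
        part2 = fstats.f4(panel, "A", "B", "O", "D", blocks).estimate
        assert whole == pytest.approx(part1 + part2, abs=1e-12)

    def test_matches_brute_force(self, four_pop_panel):
        panel, blocks = four_pop_panel
        small = panel.take_sites(np.arange(600))
        sblocks = fstats.make_blocks(small.sites, "count", 100)
        est = fstats.f4(small, "A", "B", "C", "D", sblocks).estimate
        assert est == pytest.approx(brute_f4(small, "A", "B", "C", "D"), abs=1e-12)

    def test_null_tree_rarely_significant(self):
        """On a clean tree ((A,B),(C,D)) the f4 Z score stays below 3."""
        graph = AdmixtureGraph(
            [
                DriftEdge("root", "ab", 0.04),
                DriftEdge("ab", "A", 0.03),
                DriftEdge("ab", "B", 0.03),
                DriftEdge("root", "cd", 0.04),
                DriftEdge("cd", "C", 0.03),
                DriftEdge("cd", "D", 0.03),
            ]
        )
        hits = 0
        n_reps = 100
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            freqs = synthgen.simulate_frequencies(graph, 5_000, rng)
            panel = synthgen.sample_panel(freqs, _complete_specs(["A", "B", "C", "D"]), rng)
            blocks = fstats.make_blocks(panel.sites, "count", 100)
            if abs(fstats.f4(panel, "A", "B", "C", "D", blocks).z_score) < 3:
                hits += 1
        assert hits / n_reps >= 0.95


class TestDStat:
    def test_same_population_first_pair_zero(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r = fstats.d_stat(panel, "A", "A", "C", "D", blocks)
        assert r.estimate == 0.0

    def test_swap_last_pair_flips_sign(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r1 = fstats.d_stat(panel, "A", "B", "C", "D", blocks)
        r2 = fstats.d_stat(panel, "A", "B", "D", "C", blocks)
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-15)

    def test_matches_brute_force_with_missingness(self):
        """Blocked ratio estimator equals the per-site loop oracle to 1e-12,
        including panels with missing calls."""
        graph = AdmixtureGraph(
            [
                DriftEdge("root", "W", 0.05),
                DriftEdge("root", "anc", 0.03),
                DriftEdge("anc", "X", 0.04),
                DriftEdge("anc", "yz", 0.03),
                DriftEdge("yz", "Y", 0.02),
                DriftEdge("yz", "Z", 0.02),
            ]
        )
        rng = np.random.default_rng(5)
        freqs = synthgen.simulate_frequencies(graph, 1000, rng)
        specs = [SampleSpec(p, n=2, ploidy=1, mean_depth=2.0) for p in "WXYZ"]
        panel = synthgen.sample_panel(freqs, specs, rng)
        blocks = fstats.make_blocks(panel.sites, "count", 37)
        est = fstats.d_stat(panel, "W", "X", "Y", "Z", blocks).estimate
        assert est == pytest.approx(brute_d(panel, "W", "X", "Y", "Z"), abs=1e-12)

    def test_equals_pattern_counting_for_haploid_singletons(self):
        graph = AdmixtureGraph(
            [
                DriftEdge("root", "W", 0.05),
                DriftEdge("root", "anc", 0.05),
                DriftEdge("anc", "X", 0.05),
                DriftEdge("anc", "yz", 0.04),
                DriftEdge("yz", "Y", 0.03),
                DriftEdge("yz", "Z", 0.03),
            ]
        )
        rng = np.random.default_rng(9)
        freqs = synthgen.simulate_frequencies(graph, 1000, rng)
        specs = [SampleSpec(p, n=1, ploidy=1, mean_depth=None) for p in "WXYZ"]
        panel = synthgen.sample_panel(freqs, specs, rng)
        blocks = fstats.make_blocks(panel.sites, "count", 100)
        est = fstats.d_stat(panel, "W", "X", "Y", "Z", blocks).estimate
        assert est == pytest.approx(abba_baba_d(panel, "W", "X", "Y", "Z"), abs=1e-12)

    def test_gene_flow_detected_with_correct_sign(self):
        """Admixture from P4's lineage into P2 drives |Z| past 3 with the
        sign predicted by the moment oracle."""
        graph = AdmixtureGraph(
            [
                DriftEdge("root", "anc1", 0.06),
                DriftEdge("root", "anc2", 0.06),
                DriftEdge("anc1", "W", 0.03),
                DriftEdge("anc1", "X0", 0.02),
                DriftEdge("anc2", "Y", 0.03),
                DriftEdge("anc2", "Z", 0.08),
                DriftEdge("Xmix", "X", 0.01),
            ],
            [AdmixtureEvent("Xmix", "Z", "X0", 0.1)],
        )
        expected_sign = np.sign(synthgen.expected_f4(graph, "W", "X", "Y", "Z"))
        rng = np.random.default_rng(3)
        freqs = synthgen.simulate_frequencies(graph, 100_000, rng)
        panel = synthgen.sample_panel(freqs, _complete_specs(["W", "X", "Y", "Z"], n=8), rng)
        blocks = fstats.make_blocks(panel.sites, "span", 5_000_000)
        r = fstats.d_stat(panel, "W", "X", "Y", "Z", blocks)
        assert abs(r.z_score) > 3
        assert np.sign(r.estimate) == expected_sign


class TestF4Ratio:
    def test_target_equals_dog_reference_gives_one(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r = fstats.f4_ratio(panel, "A", "O", "C", "C", "D", blocks)
        assert r.estimate == 1.0

    def test_target_equals_wolf_reference_gives_zero(self, four_pop_panel):
        panel, blocks = four_pop_panel
        r = fstats.f4_ratio(panel, "A", "O", "D", "C", "D", blocks)
        assert r.estimate == 0.0

    def test_weak_denominator_flagged(self, four_pop_panel):
        panel, blocks = four_pop_panel
        # A and B are sisters: f4(A,O;A?,..) with symmetric C,D roles is ~0
        r = fstats.f4_ratio(panel, "C", "D", "A", "A", "B", blocks)
        assert r.warning == "denominator_not_significant"


class TestInvariances:
    def test_polarity_flip_leaves_statistics_unchanged(self, four_pop_panel):
        panel, blocks = four_pop_panel
        flipped_calls = panel.calls.copy()
        ploidy = panel.samples["ploidy"].to_numpy()
        ok = flipped_calls != genodata.MISSING
        flipped_calls = np.where(ok, ploidy[np.newaxis, :] - flipped_calls, flipped_calls)
        flipped = genodata.GenotypePanel(panel.sites, panel.samples, flipped_calls)
        for fn, args in (
            (fstats.f3, ("A", "B", "O")),
            (fstats.f4, ("A", "B", "C", "D")),
            (fstats.d_stat, ("A", "B", "C", "D")),
        ):
            r1 = fn(panel, *args, blocks)
            r2 = fn(flipped, *args, blocks)
            assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
            assert r1.jackknife_se == pytest.approx(r2.jackknife_se, abs=1e-12)


class TestOutgroupF3Matrix:
    def test_two_populations_single_pair(self, four_pop_panel):
        panel, blocks = four_pop_panel
        mat = fstats.outgroup_f3_matrix(panel, ["A", "B"], "O", blocks)
        pair = fstats.f3(panel, "A", "B", "O", blocks).estimate
        assert mat.loc["A", "B"] == pair
        assert mat.loc["B", "A"] == pair
        assert np.isnan(mat.loc["A", "A"])

    def test_low_coverage_samples_excluded(self):
        graph = AdmixtureGraph(
            [
                DriftEdge("root", "O", 0.08),
                DriftEdge("root", "ab", 0.05),
                DriftEdge("ab", "A", 0.03),
                DriftEdge("ab", "B", 0.03),
            ]
        )
        rng = np.random.default_rng(2)
        freqs = synthgen.simulate_frequencies(graph, 2000, rng)
        specs = [
            SampleSpec("O", n=2, ploidy=2, mean_depth=None),
            SampleSpec("A", n=2, ploidy=1, mean_depth=None),
            SampleSpec("B", n=2, ploidy=1, mean_depth=None),
        ]
        panel = synthgen.sample_panel(freqs, specs, rng)
        # mark one A sample as 0.05x coverage: below the 0.1x threshold
        panel.samples.loc[2, "coverage"] = 0.05
        blocks = fstats.make_blocks(panel.sites, "count", 100)
        mat = fstats.outgroup_f3_matrix(panel, ["A", "B"], "O", blocks, min_coverage=0.1)
        kept = panel.take_samples(np.array([0, 1, 3, 4, 5]))
        expected = fstats.f3(kept, "A", "B", "O", blocks).estimate
        assert mat.loc["A", "B"] == expected
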