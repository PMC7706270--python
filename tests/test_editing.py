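import numpy as np
import pytest

from otscan.editing import allele_bias_test, allele_bias_tests, \
    detect_large_indels, editing_efficiency, indel_start_profile, \
    subtract_background
from otscan.io import SiteRecord
from otscan.sim import SimConfig, simulate_amplicons, \
    simulate_genome_with_targets, PlantSpec
from otscan.assign import GuideRNA

from conftest import make_read
from _oracles import binom_two_sided_minlike, recount_indel_starts


def cut_site(pos=5000, contig="c1"):
    return SiteRecord(contig=contig, position=pos, start=pos, end=pos + 1)


class TestIndelProfile:
    def test_direct_ratio_at_cut(self):
        site = cut_site()
        reads = [make_read(4000, 6000, f"d{i}", indels=[(5000, "del", 2)])
                 for i in range(5)]
        reads += [make_read(4000, 6000, f"c{i}") for i in range(5)]
        profile = indel_start_profile(reads, site, half_window=1000)
        assert profile.pct_del[5000 - profile.start] == 50.0
        nonzero = np.flatnonzero(np.nan_to_num(profile.pct_del))
        assert list(nonzero) == [5000 - profile.start]

    def test_no_indels_all_zero(self):
        site = cut_site()
        reads = [make_read(4500, 5500, f"r{i}") for i in range(4)]
        profile = indel_start_profile(reads, site, half_window=400)
        assert np.nanmax(profile.pct_ins) == 0.0
        assert np.nanmax(profile.pct_del) == 0.0

    def test_uncovered_positions_are_nan(self):
        site = cut_site()
        reads = [make_read(4900, 5100, "r0")]
        profile = indel_start_profile(reads, site, half_window=500)
        assert np.isnan(profile.pct_ins[0])
        assert profile.pct_ins[5000 - profile.start] == 0.0

    def test_zero_reads_warns_all_nan(self, caplog):
        with caplog.at_level("WARNING", logger="otscan"):
            profile = indel_start_profile([], cut_site(), half_window=100)
        assert np.all(np.isnan(profile.pct_ins))

    def test_matches_exhaustive_recount(self):
        rng = np.random.default_rng(8)
        site = cut_site()
        reads = []
        for i in range(200):
            s = int(rng.integers(3500, 5000))
            e = s + int(rng.integers(300, 1500))
            indels = []
            if rng.random() < 0.5:
                pos = int(rng.integers(s + 1, e - 5))
                kind = "ins" if rng.random() < 0.5 else "del"
                indels.append((pos, kind, int(rng.integers(1, 4))))
            reads.append(make_read(s, e, f"r{i}", indels=indels))
        profile = indel_start_profile(reads, site, half_window=1000)
        cov, ins, dele = recount_indel_starts(reads, "c1", profile.start,
                                              profile.end)
        assert np.array_equal(profile.coverage, cov)
        counts_back = np.round(
            np.nan_to_num(profile.pct_ins) * cov / 100.0).astype(int)
        assert np.array_equal(counts_back, ins)
        counts_back_del = np.round(
            np.nan_to_num(profile.pct_del) * cov / 100.0).astype(int)
        assert np.array_equal(counts_back_del, dele)


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        site = cut_site()
        reads = [make_read(4000, 6000, f"r{i}",
                           indels=[(4800 + i, "del", 1)]) for i in range(10)]
        profile = indel_start_profile(reads, site, half_window=1000)
        delta = subtract_background(profile, profile)
        assert np.nanmax(np.abs(delta.d_ins)) == 0.0
        assert np.nanmax(np.abs(delta.d_del)) == 0.0

    def test_arithmetic_and_antisymmetry(self):
        site = cut_site()
        edited = [make_read(4000, 6000, f"e{i}", indels=[(5000, "del", 2)])
                  for i in range(5)] + \
                 [make_read(4000, 6000, f"ec{i}") for i in range(5)]
        wt = [make_read(4000, 6000, "w0", indels=[(5000, "del", 1)])] + \
             [make_read(4000, 6000, f"wc{i}") for i in range(49)]
        pe = indel_start_profile(edited, site, half_window=500)
        pw = indel_start_profile(wt, site, half_window=500)
        d = subtract_background(pe, pw)
        k = 5000 - d.start
        assert d.d_del[k] == pytest.approx(50.0 - 2.0)
        d_rev = subtract_background(pw, pe)
        assert d_rev.d_del[k] == pytest.approx(-(50.0 - 2.0))

    def test_nan_propagates(self):
        site = cut_site()
        pe = indel_start_profile([make_read(4900, 5100, "r")], site,
                                 half_window=500)
        pw = indel_start_profile([make_read(4500, 5500, "w")], site,
                                 half_window=500)
        d = subtract_background(pe, pw)
        assert np.isnan(d.d_ins[0])

    def test_window_mismatch_rejected(self):
        site = cut_site()
        pe = indel_start_profile([make_read(4000, 6000, "r")], site,
                                 half_window=500)
        pw = indel_start_profile([make_read(4000, 6000, "r")], site,
                                 half_window=400)
        with pytest.raises(ValueError):
            subtract_background(pe, pw)


class TestEditingEfficiency:
    def test_arithmetic(self):
        site = cut_site()
        edited = [make_read(4000, 6000, f"e{i}", indels=[(5001, "del", 3)])
                  for i in range(60)]
        edited += [make_read(4000, 6000, f"ec{i}") for i in range(40)]
        wt = [make_read(4000, 6000, "w0", indels=[(5005, "ins", 1)]),
              make_read(4000, 6000, "w1", indels=[(4995, "del", 1)])]
        wt += [make_read(4000, 6000, f"wc{i}") for i in range(98)]
        res = editing_efficiency(edited, wt, site, core=20)
        assert res["efficiency"] == pytest.approx(0.58)
        assert res["edited_fraction"] == pytest.approx(0.60)

    def test_identical_samples_give_zero(self):
        site = cut_site()
        reads = [make_read(4000, 6000, f"r{i}",
                           indels=[(5000, "del", 1)] if i < 3 else [])
                 for i in range(10)]
        assert editing_efficiency(reads, reads, site)["efficiency"] == 0.0

    def test_non_spanning_reads_excluded(self):
        site = cut_site()
        spanning = [make_read(4000, 6000, f"s{i}") for i in range(5)]
        truncated = [make_read(4990, 5010, f"t{i}",
                               indels=[(5000, "del", 1)]) for i in range(5)]
        res = editing_efficiency(spanning + truncated, spanning, site, core=20)
        assert res["n_edited_reads"] == 5  # truncated reads don't span +-20

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            editing_efficiency([], [make_read(0, 10000)], cut_site())

    def test_recovers_planted_edit_rates(self):
        guide = GuideRNA(name="g", spacer="ACGTACGTACGTACGTACGT")
        cfg = SimConfig(genome_length=20_000)
        ref, _ = simulate_genome_with_targets(
            cfg, [guide], [PlantSpec(guide="g", position=10_000)], seed=2)
        site = cut_site(pos=10_000, contig="sim1")
        for rate in (0.1, 0.6):
            estimates = []
            for seed in range(5):
                e, w, _ = simulate_amplicons(ref, 10_000, edit_rate=rate,
                                             n_reads=500, seed=seed)
                estimates.append(
                    editing_efficiency(e, w, site)["efficiency"])
            assert abs(float(np.mean(estimates)) - rate) < 0.05


class TestLargeIndels:
    def test_single_large_insertion(self):
        site = cut_site()
        reads = [make_read(4000, 6000, "r0", indels=[(5000, "ins", 120)])]
        [cluster] = detect_large_indels(reads, site)
        assert cluster.kind == "ins" and cluster.support == 1

    def test_threshold_excludes_short_events(self):
        site = cut_site()
        reads = [make_read(4000, 6000, f"r{i}", indels=[(5000, "del", 200)])
                 for i in range(3)]
        reads.append(make_read(4000, 6000, "r3", indels=[(5000, "del", 40)]))
        clusters = detect_large_indels(reads, site, min_len=50)
        assert len(clusters) == 1 and clusters[0].support == 3

    def test_distinct_lengths_form_distinct_clusters(self):
        site = cut_site()
        reads = [make_read(4000, 6000, "a", indels=[(5000, "del", 100)]),
                 make_read(4000, 6000, "b", indels=[(5000, "del", 300)])]
        assert len(detect_large_indels(reads, site)) == 2

    def test_simulated_vector_insertion_support(self):
        guide = GuideRNA(name="g", spacer="ACGTACGTACGTACGTACGT")
        cfg = SimConfig(genome_length=20_000)
        ref, _ = simulate_genome_with_targets(
            cfg, [guide], [PlantSpec(guide="g", position=10_000)], seed=3)
        e, _, _ = simulate_amplicons(ref, 10_000, edit_rate=0.3, n_reads=500,
                                     seed=9, large_insert=(300, 0.2))
        clusters = detect_large_indels(e, cut_site(pos=10_000, contig="sim1"))
        big = [c for c in clusters if c.kind == "ins" and c.length >= 250]
        assert len(big) == 1
        # binomial 95% CI around 0.2 * 500
        sd = np.sqrt(500 * 0.2 * 0.8)
        assert abs(big[0].support - 100) < 1.96 * sd + 1


class TestAlleleBias:
    def test_null_case(self):
        res = allele_bias_test(50, 100, 0.5)
        assert res.p_value == pytest.approx(1.0)
        assert not res.biased

    def test_paper_style_extreme_bias(self):
        res = allele_bias_test(101, 106, 17 / 23)
        assert res.p_value < 1e-6
        assert res.biased

    def test_zero_successes(self):
        res = allele_bias_test(0, 10, 0.5)
        assert res.p_value == pytest.approx(2 * 0.5 ** 10)
        assert res.biased

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            ours = allele_bias_test(k, n, p).p_value
            oracle = binom_two_sided_minlike(k, n, p)
            assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            allele_bias_test(1, 0, 0.5)
        with pytest.raises(ValueError):
            allele_bias_test(5, 10, 1.0)
        with pytest.raises(ValueError):
            allele_bias_test(11, 10, 0.5)

    def test_bh_correction_across_sites(self):
        cases = [(50, 100, 0.5)] * 5 + [(95, 100, 0.5)]
        results = allele_bias_tests(cases, alpha=0.01)
        assert results[-1].biased
        assert not any(r.biased for r in results[:-1])
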