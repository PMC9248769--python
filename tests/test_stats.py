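import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagepan.clonotyping import ClonotypeKey, RepertoireSample
from phagepan.stats import (
    diversity,
    diversity_report,
    dominance,
    evenness,
    shannon_entropy,
    spectratype,
    subsample,
    total_unique_ratio,
    unique_cdrh3_ratio,
)

AA = "ACDEFGHIKLMNPQRSTVY"


def make_sample(counts, label="s", length=10):
    keyed = {}
    for i, c in enumerate(counts):
        aa = "C"
        n = i
        for _ in range(length - 2):
            aa += AA[n % len(AA)]
            n //= len(AA)
        keyed[ClonotypeKey("IGHV1-1", "IGHJ1", 0, 0, 3 * length - 6, aa + "W")] = c
    return RepertoireSample(label=label, counts=Counter(keyed),
                            total_identified=sum(counts))


def entropy_oracle(props):
    """Independent direct-summation oracle for Shannon entropy."""
    return -sum(p * math.log(p) for p in props)


class TestShannonEntropy:
    def test_point_mass_is_zero(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_uniform_closed_form(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4))

    def test_matches_direct_summation_oracle(self):
        props = (0.5, 0.3, 0.2)
        expect = entropy_oracle(props)
        assert expect == pytest.approx(1.02965, abs=1e-5)
        assert shannon_entropy(props) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("bad", [[], [0.5, 0.5, 0.0], [0.7, -0.3, 0.6], [0.2, 0.2]])
    def test_invalid_proportions_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_entropy(bad)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=40))
    def test_entropy_bounded_by_log_richness(self, counts):
        """exp(H) <= S with equality iff uniform."""
        p = np.array(counts) / sum(counts)
        H = shannon_entropy(p)
        assert H <= math.log(len(counts)) + 1e-9
        if len(set(counts)) == 1:
            assert H == pytest.approx(math.log(len(counts)))


class TestDiversityEvennessDominance:
    def test_uniform_diversity_equals_richness(self):
        s = make_sample([7] * 95)
        assert diversity(s) == pytest.approx(95.0)

    def test_single_clonotype(self):
        s = make_sample([50])
        assert diversity(s) == pytest.approx(1.0)
        assert evenness(s) is None
        assert dominance(s) == 100.0

    def test_skewed_counts_from_entropy_oracle(self):
        s = make_sample([5, 3, 2])
        H = entropy_oracle([0.5, 0.3, 0.2])
        assert diversity(s) == pytest.approx(math.exp(H))
        assert diversity(s) == pytest.approx(2.800, abs=1e-3)
        assert evenness(s) == pytest.approx(H / math.log(3))
        assert evenness(s) == pytest.approx(0.9372, abs=1e-4)

    def test_uniform_evenness_is_one(self):
        for S in (2, 5, 40):
            assert evenness(make_sample([9] * S)) == pytest.approx(1.0)

    def test_dominance_uniform_and_table_magnitude(self):
        assert dominance(make_sample([5] * 4)) == 25.0
        counts = [1235] + [8765 // 99 + (1 if i < 8765 % 99 else 0) for i in range(99)]
        assert dominance(make_sample(counts)) == pytest.approx(12.35)

    def test_empty_sample_rejected(self):
        empty = RepertoireSample(label="x", counts=Counter(), total_identified=0)
        for fn in (diversity, evenness, dominance, spectratype, unique_cdrh3_ratio):
            with pytest.raises(ValueError):
                fn(empty)


class TestSubsample:
    def test_saturation_returns_sample_unchanged(self):
        s = make_sample([100] * 200)  # 20,000 reads
        assert subsample(s, depth=50_000, seed=0) is s

    def test_seed_reproducibility(self):
        s = make_sample([997] * 100)
        a = subsample(s, depth=1000, seed=42)
        b = subsample(s, depth=1000, seed=42)
        assert a.counts == b.counts
        assert a.n_reads == 1000

    def test_counts_match_hypergeometric_expectation(self):
        s = make_sample([100] * 100)  # uniform, 10,000 reads
        sub = subsample(s, depth=1000, seed=7)
        counts = np.array([sub.counts.get(k, 0) for k in s.counts])
        # each count ~ Hypergeom(10000, 100, 1000): mean 10, sd ~3
        assert counts.mean() == pytest.approx(10.0)
        assert np.all(counts <= 10 + 5 * 3)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            subsample(make_sample([5]), depth=0, seed=0)

    def test_dominance_unbiased_over_seeds(self):
        """Mean subsampled dominance tracks full-sample dominance when one
        clonotype clearly dominates (ties would bias the sampled maximum)."""
        rng = np.random.default_rng(3)
        s = make_sample([1500] + list(rng.integers(10, 500, size=80)))
        full = dominance(s)
        doms = [dominance(subsample(s, depth=2000, seed=k)) for k in range(20)]
        se = np.std(doms, ddof=1) / np.sqrt(len(doms))
        assert abs(np.mean(doms) - full) <= 3 * max(se, 1e-9) + 0.05


class TestSpectratype:
    def test_single_length(self):
        sp = spectratype(make_sample([10, 5], length=12))
        assert sp.percent_by_length == {10: 100.0}
        assert sp.mean_length == 10

    def test_percents_sum_to_100(self, small_campaign):
        _, _, samples = small_campaign
        for s in samples:
            sp = spectratype(s)
            assert sum(sp.percent_by_length.values()) == pytest.approx(100.0, abs=1e-6)

    def test_default_library_mean_length(self, small_library):
        """Bell-shaped CDRH3 law: mean length 11-13 aa."""
        _, _, sample = small_library
        sp = spectratype(sample)
        assert 11.0 <= sp.mean_length <= 13.0

    def test_read_weighted_not_clonotype_weighted(self):
        s = make_sample([90, 5], length=12)
        # one more clonotype with a different junction length
        long_key = ClonotypeKey("IGHV1-1", "IGHJ1", 0, 0, 42, "C" + "A" * 14 + "W")
        s.counts[long_key] = 5
        s.total_identified += 5
        sp = spectratype(s)
        assert sp.percent_by_length[10] == pytest.approx(95.0)
        assert sp.percent_by_length[14] == pytest.approx(5.0)


class TestUniqueCdrh3Ratio:
    @pytest.mark.parametrize(
        "total, unique, ratio",
        [
            (12_000_000, 1_200_000, 10),
            (820_000, 18_926, 43),
            (240_000, 24_167, 10),
            (7, 7, 1),
        ],
    )
    def test_printed_ratios(self, total, unique, ratio):
        assert total_unique_ratio(total, unique) == ratio

    def test_all_reads_identical(self):
        s = make_sample([123])
        total, unique, ratio = unique_cdrh3_ratio(s)
        assert (total, unique, ratio) == (123, 1, 123)


def test_monotone_collapse_on_expected_frequencies(small_campaign):
    """Dispersed selection strictly decreases expected D and E (no sampling)."""
    cfg, truth, _ = small_campaign
    for r in range(cfg.n_rounds):
        p0 = truth.expected_freqs(r)
        p1 = truth.expected_freqs(r + 1)
        H0, H1 = shannon_entropy(p0), shannon_entropy(p1)
        assert math.exp(H1) < math.exp(H0)
        assert H1 / math.log(len(p1)) < H0 / math.log(len(p0))


def test_diversity_report_consistency(small_campaign):
    _, _, samples = small_campaign
    rep = diversity_report(samples[0], depth=2000, seed=5)
    assert rep.diversity_D == pytest.approx(math.exp(rep.shannon_H))
    assert 1.0 <= rep.diversity_D <= rep.n_clonotypes_obs
    assert rep.evenness_E is None or 0.0 <= rep.evenness_E <= 1.0
    assert 0.0 < rep.dominance_pct <= 100.0
    assert rep.depth == 2000
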