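"""Category banding, Sørensen machinery, indicator selection, frequencies."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavebio import (CategoryPriors, ConditionCategory, SampleRecord,
                     assign_category, estimate_frequencies, select_indicators,
                     sorensen_index, summarize_frequencies, taxon_contributions)
from wavebio.training import FrequencyTable, occurrence_frequency, round_half_up


def _sample(i, taxa, bap=None, category=None):
    return SampleRecord(f"s{i}", frozenset(taxa), bap=bap, category=category)


class TestAssignCategory:
    @pytest.mark.parametrize("bap, expected", [
        (8.0, ConditionCategory.NON),
        (7.5, ConditionCategory.NON),
        (6.0, ConditionCategory.SLIGHT),
        (5.0, ConditionCategory.SLIGHT),
        (4.0, ConditionCategory.MODERATE),
        (2.5, ConditionCategory.SEVERE),
        (0.0, ConditionCategory.SEVERE),
        (10.0, ConditionCategory.NON),
    ])
    def test_bands(self, bap, expected):
        assert assign_category(bap) is expected

    @pytest.mark.parametrize("bap, impaired", [
        (8.0, False), (6.0, False), (5.0, True), (4.88, True), (2.0, True),
    ])
    def test_impaired_grouping_cuts_at_5(self, bap, impaired):
        # BAP exactly 5 is "slight" in the four-tier banding yet impaired
        # in the two-way grouping
        assert _sample(0, set(), bap=bap).is_impaired() is impaired

    @pytest.mark.parametrize("bap", [-0.1, 10.1])
    def test_out_of_range(self, bap):
        with pytest.raises(ValueError):
            assign_category(bap)


class TestSorensen:
    @pytest.mark.parametrize("a, b, expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"x", "y", "z"}, {"y", "z", "w"}, 2 * 2 / 6),
        (set(), set(), 0.0),
        (set(), {"x"}, 0.0),
    ])
    def test_values(self, a, b, expected):
        assert sorensen_index(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.sets(st.integers(0, 12)), st.sets(st.integers(0, 12)))
    def test_symmetric_and_bounded(self, a, b):
        s = sorensen_index(a, b)
        assert s == sorensen_index(b, a)
        assert 0.0 <= s <= 1.0
        if a or b:
            assert (s == 1.0) == (a == b)


def brute_force_contributions(samples):
    """Independent pair-enumeration oracle for taxon_contributions."""
    per_taxon, total = {}, 0.0
    for a, b in itertools.combinations(samples, 2):
        denom = len(a.taxa) + len(b.taxa)
        if denom == 0:
            continue
        total += 2 * len(a.taxa & b.taxa) / denom
        for t in a.taxa & b.taxa:
            per_taxon[t] = per_taxon.get(t, 0.0) + 2 / denom
    labels = sorted({t for s in samples for t in s.taxa})
    if total <= 0:
        return {t: 0.0 for t in labels}
    return {t: per_taxon.get(t, 0.0) / total for t in labels}


class TestTaxonContributions:
    @pytest.mark.parametrize("taxa_sets, expected", [
        ([{"x"}, {"x"}], {"x": 1.0}),
        ([{"x", "y"}, {"x", "y"}], {"x": 0.5, "y": 0.5}),
        ([{"x", "y"}, {"x", "z"}], {"x": 1.0, "y": 0.0, "z": 0.0}),
    ])
    def test_examples(self, taxa_sets, expected):
        samples = [_sample(i, t) for i, t in enumerate(taxa_sets)]
        got = taxon_contributions(samples)
        assert got == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.sets(st.sampled_from("abcdefg")), min_size=2, max_size=8))
    def test_matches_pair_enumeration_and_sums_to_one(self, taxa_sets):
        samples = [_sample(i, t) for i, t in enumerate(taxa_sets)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = taxon_contributions(samples)
        oracle = brute_force_contributions(samples)
        assert got == pytest.approx(oracle, abs=1e-12)
        if any(v > 0 for v in oracle.values()):
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_shared_taxa_warns_and_zeroes(self):
        samples = [_sample(0, {"x"}), _sample(1, {"y"})]
        with pytest.warns(UserWarning):
            assert taxon_contributions(samples) == {"x": 0.0, "y": 0.0}

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            taxon_contributions([_sample(0, {"x"})])


class TestSelectIndicators:
    def _training_set(self):
        # 10 non-impacted + 10 impaired samples over a small community.
        # "good" occurs in 8/10 non and 1/10 impaired samples (the impaired
        # occurrence shares little similarity there); "bad" mirrors it;
        # "ubiquitous" is everywhere; "flat" has equal frequency.
        non, imp = [], []
        for i in range(10):
            taxa = {"ubiquitous"}
            if i < 8:
                taxa.add("good")
            if i < 5:
                taxa.add("flat")
            non.append(_sample(f"n{i}", taxa, bap=9.0))
        for i in range(10):
            taxa = set()
            if i < 9:  # frequency edge for "ubiquitous" is 10/10 vs 9/10
                taxa.add("ubiquitous")
            if i < 8:
                taxa.add("bad")
            if i == 0:
                taxa.add("good")
            if i < 5:
                taxa.add("flat")
            imp.append(_sample(f"i{i}", taxa, bap=2.0))
        return non + imp

    def test_directional_selection(self):
        registry = select_indicators(self._training_set())
        assert registry.direction("good") == "unimpaired"
        assert registry.direction("bad") == "impaired"

    def test_equal_frequency_taxon_not_selected(self):
        registry = select_indicators(self._training_set())
        assert registry.direction("flat") is None

    def test_high_opposing_contribution_blocks_selection(self):
        # "ubiquitous" dominates similarity in both pools, so even a slight
        # frequency edge could not make it an indicator
        registry = select_indicators(self._training_set())
        assert registry.direction("ubiquitous") is None

    def test_small_pool_is_an_error(self):
        samples = [_sample(0, {"x"}, bap=9.0), _sample(1, {"x"}, bap=9.0),
                   _sample(2, {"y"}, bap=2.0)]
        with pytest.raises(ValueError, match="impaired pool"):
            select_indicators(samples)


class TestEstimateFrequencies:
    def _labelled(self):
        samples = [
            _sample(0, {"Perlidae", "Asellidae"}, bap=9.0),
            _sample(1, {"Perlidae"}, bap=8.0),
            _sample(2, set(), bap=8.5),
            _sample(3, {"Asellidae"}, bap=9.5),
            _sample(4, {"Perlidae"}, bap=6.0),
            _sample(5, {"Asellidae"}, bap=6.5),
            _sample(6, {"Asellidae"}, bap=2.0),
            _sample(7, {"Asellidae"}, bap=4.0),
        ]
        return samples

    def test_containment_proportions(self, registry):
        table, priors = estimate_frequencies(self._labelled(), registry)
        assert table.freq("Perlidae") == pytest.approx((0.5, 0.5, 0.0))
        assert table.freq("Asellidae") == pytest.approx((0.5, 0.5, 1.0))
        # absent-from-impaired frequency is exactly zero, not smoothed
        assert table.freq("Perlidae")[2] == 0.0

    def test_priors_from_counts(self):
        priors = CategoryPriors.from_counts(406, 728, 287)
        assert priors.as_tuple() == pytest.approx((0.2857, 0.5123, 0.2020),
                                                  abs=5e-5)
        assert sum(priors.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_category_is_an_error(self, registry):
        samples = [_sample(0, {"Perlidae"}, bap=9.0),
                   _sample(1, {"Perlidae"}, bap=6.0)]
        with pytest.raises(ValueError, match="impaired"):
            estimate_frequencies(samples, registry)

    def test_unlabelled_sample_is_an_error(self, registry):
        with pytest.raises(ValueError, match="lack"):
            estimate_frequencies([_sample(0, {"Perlidae"})], registry)


class TestSummaries:
    def test_packaged_table_iqr_endpoints(self, registry, freq):
        # printed interquartile ranges of the reference frequency table
        summary = summarize_frequencies(freq, registry)
        unimp, imp = summary["unimpaired"], summary["impaired"]
        assert (unimp["non"]["q25"], unimp["non"]["q75"]) == (0.07, 0.34)
        assert (unimp["slight"]["q25"], unimp["slight"]["q75"]) == (0.02, 0.22)
        assert (imp["impaired"]["q25"], imp["impaired"]["q75"]) == (0.05, 0.26)
        assert (imp["non"]["q25"], imp["non"]["q75"]) == (0.0, 0.05)

    def test_constant_column_degenerate(self, registry):
        table = FrequencyTable()
        for label in registry.labels():
            table.set(label, (0.3, 0.3, 0.3))
        summary = summarize_frequencies(table, registry)
        for direction in summary.values():
            for stats in direction.values():
                assert stats["median"] == stats["q25"] == stats["q75"] == 0.3

    def test_round_half_up(self):
        assert round_half_up(0.175) == 0.18
        assert round_half_up(0.085) == 0.09
        assert round_half_up(11.75, 0) == 12.0


def test_occurrence_frequency_counts_samples_not_individuals():
    samples = [_sample(0, {"x", "y"}), _sample(1, {"x"}), _sample(2, set()),
               _sample(3, {"x"})]
    assert occurrence_frequency(samples) == {"x": 0.75, "y": 0.25}
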