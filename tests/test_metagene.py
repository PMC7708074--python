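"""Binning, profile normalization, region fractions, boxplot convention and
heatmap ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cracmap import metagene
from cracmap.metagene import (BinScheme, MetageneError, aggregate_metagene,
                              bin_index, boxplot_summary, heatmap_matrix,
                              profiles_from_assignment, region_fraction,
                              transcript_profile)

from conftest import make_annotation, make_transcript


def brute_force_bin(t, m, scheme=BinScheme()):
    """Per-position oracle built straight from the definition."""
    region = t.region_at(m)
    if region == "utr5":
        d, L, n, off = m, t.utr5_len, scheme.n_utr5, 0
    elif region == "cds":
        d, L = m - t.utr5_len, t.cds_len
        n, off = scheme.n_cds, scheme.n_utr5
    else:
        d, L = m - t.utr5_len - t.cds_len, t.utr3_len
        n, off = scheme.n_utr3, scheme.n_utr5 + scheme.n_cds
    return off + min(int(np.floor(d * n / L)), n - 1)


class TestBinIndex:
    @pytest.mark.parametrize("m,expected", [
        (50, 5),      # floor(50*10/100) in the 5'UTR block
        (100, 10),    # first CDS base lands at the CDS block offset
        (99, 9), (999, 109),
    ])
    def test_block_layout(self, m, expected):
        t = make_transcript(utr5=100, cds=900, utr3=200)
        assert bin_index(t, m) == expected

    def test_last_utr3_base_clips_into_bin_119(self):
        t = make_transcript(utr5=100, cds=900, utr3=200)
        assert bin_index(t, t.mature_length - 1) == 119

    def test_zero_length_region_excluded(self):
        t = make_transcript(exons=((0, 1000),), utr5=0, cds=900, utr3=100)
        with pytest.raises(MetageneError):
            bin_index(t, 10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_random_transcripts(self, seed):
        rng = np.random.default_rng(seed)
        u5 = int(rng.integers(1, 60))
        cds = int(rng.integers(3, 400))
        u3 = int(rng.integers(1, 80))
        t = make_transcript(exons=((0, u5 + cds + u3),),
                            utr5=u5, cds=cds, utr3=u3)
        for m in range(t.mature_length):
            assert bin_index(t, m) == brute_force_bin(t, m)


class TestTranscriptProfile:
    def test_point_mass(self):
        t = make_transcript(utr5=100, cds=900, utr3=200)
        # bin 115 covers 3'UTR offsets 100..119 (20 nt per bin here)
        pos = [t.utr5_len + t.cds_len + 100] * 4
        p = transcript_profile(t, pos)
        assert p[115] == 1.0 and p.sum() == 1.0

    def test_two_point_split(self):
        t = make_transcript(utr5=100, cds=900, utr3=200)
        pos = [50, t.utr5_len + t.cds_len + 100]
        p = transcript_profile(t, pos)
        assert p[5] == 0.5 and p[115] == 0.5

    def test_zero_reads_rejected(self):
        t = make_transcript()
        with pytest.raises(MetageneError):
            transcript_profile(t, [])

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(2)
        t = make_transcript(utr5=37, cds=411, utr3=91)
        pos = rng.integers(0, t.mature_length, size=50)
        p = transcript_profile(t, pos)
        oracle = np.zeros(120)
        for m in pos:
            oracle[brute_force_bin(t, int(m))] += 1
        assert np.allclose(p, oracle / 50)

    def test_monotone_in_utr3_mass(self):
        """Adding 3'UTR reads never decreases the 3'UTR bin mass."""
        t = make_transcript(utr5=100, cds=900, utr3=200)
        base = list(np.linspace(0, t.mature_length - 1, 20).astype(int))
        prev = transcript_profile(t, base)[110:].sum()
        utr3_pos = t.utr5_len + t.cds_len + 50
        for extra in range(1, 6):
            cur = transcript_profile(t, base + [utr3_pos] * extra)[110:].sum()
            assert cur >= prev
            prev = cur


class TestVectorizedProfiles:
    def test_agree_with_scalar_path_and_unit_sum(self, small_sim):
        assigned = small_sim["assigned"]
        tagged = assigned[assigned["role"] == "crac_tagged"]
        profiles, skipped = profiles_from_assignment(tagged, small_sim["ann"])
        assert not skipped
        sums = profiles.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        tid = profiles.index[0]
        pos = tagged.loc[tagged["tx"] == tid, "mature_pos"].astype(int)
        assert np.allclose(profiles.loc[tid].to_numpy(),
                           transcript_profile(small_sim["ann"][tid], list(pos)))


class TestAggregate:
    def test_mean_of_identical_profiles_is_identity(self, small_sim):
        cm = small_sim["cm"]
        row = np.zeros(120)
        row[115] = 1.0
        ids = cm.counts.index[:2]
        profiles = pd.DataFrame([row, row], index=ids)
        # force both transcripts through the filter
        agg, n = aggregate_metagene(profiles, cm, min_rpm=-1.0)
        assert n == 2 and np.allclose(agg, row)

    def test_aggregate_unit_sum(self, small_sim):
        assigned = small_sim["assigned"]
        tagged = assigned[assigned["role"] == "crac_tagged"]
        profiles, _ = profiles_from_assignment(tagged, small_sim["ann"])
        agg, n = aggregate_metagene(profiles, small_sim["cm"], min_rpm=100)
        assert n > 0
        assert agg.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_filter_rejected(self, small_sim):
        assigned = small_sim["assigned"]
        profiles, _ = profiles_from_assignment(
            assigned[assigned["role"] == "crac_tagged"], small_sim["ann"])
        with pytest.raises(MetageneError):
            aggregate_metagene(profiles, small_sim["cm"], min_rpm=1e12)


class TestRegionFraction:
    def test_arithmetic(self):
        rc = pd.DataFrame({"tx": ["a"], "sample": ["s"],
                           "utr5": [5], "cds": [20], "utr3": [75]})
        fr = region_fraction(rc)
        assert (fr["f5"].item(), fr["fcds"].item(), fr["f3"].item()) == \
            (0.05, 0.20, 0.75)

    def test_degenerate_and_zero_total(self):
        rc = pd.DataFrame({"tx": ["a"], "sample": ["s"],
                           "utr5": [0], "cds": [0], "utr3": [10]})
        assert region_fraction(rc)["f3"].item() == 1.0
        bad = pd.DataFrame({"tx": ["a"], "sample": ["s"],
                            "utr5": [0], "cds": [0], "utr3": [0]})
        with pytest.raises(MetageneError):
            region_fraction(bad)


class TestBoxplotSummary:
    def test_one_to_nine(self):
        # percentiles by linear interpolation: q1=3, median=5, q3=7
        s = boxplot_summary(range(1, 10))
        assert (s.q1, s.median, s.q3) == (3, 5, 7)
        assert (s.whisker_low, s.whisker_high) == (1, 9)
        assert s.outliers == ()

    def test_constant_data(self):
        s = boxplot_summary([4.2] * 7)
        assert s.q1 == s.median == s.q3 == s.whisker_low == s.whisker_high == 4.2
        assert s.outliers == ()

    def test_extreme_value_is_outlier(self):
        # with 1..9 + 100: q1=3.25, q3=7.75, fence=7.75+1.5*4.5=14.5
        s = boxplot_summary(list(range(1, 10)) + [100])
        assert s.outliers == (100,)
        assert s.whisker_high == 9

    def test_whiskers_are_attained_points(self, small_sim):
        rng = np.random.default_rng(0)
        v = rng.lognormal(0, 1, 500)
        s = boxplot_summary(v)
        assert s.whisker_low in v and s.whisker_high in v
        assert s.whisker_low >= s.q1 - 1.5 * (s.q3 - s.q1) - 1e-12
        assert s.whisker_high <= s.q3 + 1.5 * (s.q3 - s.q1) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(MetageneError):
            boxplot_summary([])


class TestHeatmap:
    def _profile(self, f3):
        row = np.zeros(120)
        row[115] = f3
        row[50] = 1 - f3
        return row

    def test_ordering_by_3utr_fraction(self):
        profiles = pd.DataFrame(
            [self._profile(0.5), self._profile(0.9), self._profile(0.1)],
            index=["b", "a", "c"])
        hm = heatmap_matrix(profiles, ordering="by_3utr_fraction")
        assert list(hm.index) == ["a", "b", "c"]

    def test_single_transcript_identity(self):
        profiles = pd.DataFrame([self._profile(0.7)], index=["x"])
        hm = heatmap_matrix(profiles)
        assert hm.shape == (1, 120)
        assert np.allclose(hm.iloc[0], profiles.iloc[0])

    def test_rows_unit_sum_random_profiles(self):
        rng = np.random.default_rng(1)
        raw = rng.random((100, 120))
        profiles = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True),
                                index=[f"t{i:03d}" for i in range(100)])
        hm = heatmap_matrix(profiles)
        assert np.allclose(hm.sum(axis=1), 1.0, atol=1e-9)
        assert sorted(hm.index) == sorted(profiles.index)
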