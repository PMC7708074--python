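"""Read assignment rules against hand-built fixtures and a per-read
brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from cracmap import assign
from cracmap.assign import (AssignmentError, CountMatrix, classify_reads,
                            count_by_region, count_per_transcript,
                            rpm_normalize)

from conftest import make_annotation, make_reads, make_transcript


def brute_force_assign(reads, ann):
    """Reference implementation: midpoint containment, longest total read
    overlap, then smallest id; same-strand only."""
    out = []
    for row in reads.itertuples(index=False):
        mid = (row.start + row.end - 1) // 2
        candidates = []
        for t in ann:
            if t.chrom != row.chrom or t.strand != row.strand:
                continue
            m = t.to_mature_coord(mid)
            if m is None:
                continue
            overlap = sum(max(0, min(row.end, e.end) - max(row.start, e.start))
                          for e in t.exons)
            candidates.append((-overlap, t.id, m))
        if candidates:
            candidates.sort()
            _, tid, m = candidates[0]
            out.append((row.sample, tid, m))
    return out


class TestTranscriptAssignment:
    def test_single_candidate(self):
        ann = make_annotation(make_transcript(exons=((100, 1400),)))
        reads = make_reads([("chr1", 100, 130, "+")])
        a = assign.assign_reads(reads, ann)
        assert list(a["tx"]) == ["tx1"] and list(a["mature_pos"]) == [14]

    def test_longest_overlap_wins(self):
        # midpoint 115 inside both; A covers the full read, B only 20 bases
        a_t = make_transcript(tid="txA", exons=((50, 1350),))
        b_t = make_transcript(tid="txB", exons=((110, 1410),))
        ann = make_annotation(a_t, b_t)
        reads = make_reads([("chr1", 100, 130, "+")])
        out = assign.assign_reads(reads, ann)
        assert list(out["tx"]) == ["txA"]

    def test_tie_broken_by_smallest_id(self):
        t1 = make_transcript(tid="txB", exons=((100, 1400),))
        t2 = make_transcript(tid="txA", exons=((100, 1400),))
        ann = make_annotation(t1, t2)
        out = assign.assign_reads(make_reads([("chr1", 200, 230, "+")]), ann)
        assert list(out["tx"]) == ["txA"]

    def test_antisense_read_unassigned(self):
        ann = make_annotation(make_transcript(exons=((100, 1400),), strand="+"))
        out = assign.assign_reads(make_reads([("chr1", 200, 230, "-")]), ann)
        assert out.empty

    def test_unknown_chromosome_named_in_error(self):
        ann = make_annotation(make_transcript())
        with pytest.raises(AssignmentError, match="chrUn"):
            assign.assign_reads(make_reads([("chrUn", 0, 30, "+")]), ann)

    def test_read_order_invariance(self, small_sim):
        reads = small_sim["reads"].iloc[:5000]
        ann = small_sim["ann"]
        shuffled = reads.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = assign.assign_reads(reads, ann)
        b = assign.assign_reads(shuffled, ann)
        key = ["chrom", "start", "end", "strand", "sample", "tx", "mature_pos"]
        pd.testing.assert_frame_equal(
            a[key].sort_values(key).reset_index(drop=True),
            b[key].sort_values(key).reset_index(drop=True),
        )

    def test_matches_brute_force_oracle(self):
        """<=100 random reads over a crowded locus equal the oracle."""
        rng = np.random.default_rng(5)
        transcripts = [
            make_transcript(tid="txA", exons=((0, 700),), utr5=50, cds=600, utr3=50),
            make_transcript(tid="txB", exons=((400, 1000), (1100, 1300)),
                            utr5=100, cds=600, utr3=100),
            make_transcript(tid="txC", strand="-", exons=((600, 1500),),
                            utr5=100, cds=700, utr3=100),
            make_transcript(tid="r1", rna_class="rRNA", exons=((650, 800),)),
        ]
        ann = make_annotation(*transcripts)
        rows = []
        for _ in range(100):
            s = int(rng.integers(0, 1600))
            rows.append(("chr1", s, s + 30, "+" if rng.random() < 0.5 else "-"))
        reads = make_reads(rows)
        got = assign.assign_reads(reads, ann)
        want = brute_force_assign(reads, ann)
        got_t = sorted(zip(got["tx"], got["mature_pos"].astype(int)))
        want_t = sorted((tid, m) for _, tid, m in want)
        assert got_t == want_t


class TestClassification:
    def test_class_priority(self):
        mrna = make_transcript(exons=((100, 1400),))
        rrna = make_transcript(tid="r1", rna_class="rRNA", exons=((100, 400),))
        ann = make_annotation(mrna, rrna)
        shares = classify_reads(make_reads([("chr1", 200, 230, "+")]), ann)
        assert shares.loc[shares["rna_class"] == "rRNA", "fraction"].item() == 1.0

    def test_all_intergenic(self):
        ann = make_annotation(make_transcript(exons=((100, 1400),)))
        shares = classify_reads(make_reads([("chr1", 1450, 1480, "+")] * 3), ann)
        assert shares.loc[shares["rna_class"] == "intergenic", "fraction"].item() == 1.0

    def test_constructed_share_tally(self):
        """6 mRNA, 3 rRNA, 1 intergenic reads -> shares 0.6/0.3/0.1."""
        mrna = make_transcript(exons=((0, 1300),))
        rrna = make_transcript(tid="r1", rna_class="rRNA", exons=((2000, 2300),))
        ann = make_annotation(mrna, rrna, genome_lengths={"chr1": 5000})
        rows = ([("chr1", 10, 40, "+")] * 6
                + [("chr1", 2100, 2130, "+")] * 3
                + [("chr1", 4000, 4030, "+")])
        shares = classify_reads(make_reads(rows), ann).set_index("rna_class")
        assert shares.loc["mRNA", "fraction"] == pytest.approx(0.6)
        assert shares.loc["rRNA", "fraction"] == pytest.approx(0.3)
        assert shares.loc["intergenic", "fraction"] == pytest.approx(0.1)

    def test_shares_sum_to_one_per_sample(self, small_sim):
        shares = classify_reads(small_sim["reads"], small_sim["ann"])
        sums = shares.groupby("sample")["fraction"].sum()
        assert np.allclose(sums, 1.0)


class TestRegionCounts:
    def test_degenerate_all_utr3(self):
        t = make_transcript(utr5=100, cds=900, utr3=300)
        ann = make_annotation(t)
        # mature 1000..1299 is the 3'UTR; place 10 read midpoints inside
        rows = [("chr1", 100 + 1010 + i * 20 - 14, 100 + 1010 + i * 20 + 16, "+")
                for i in range(10)]
        rc = count_by_region(make_reads(rows), ann)
        assert rc[["utr5", "cds", "utr3"]].values.tolist() == [[0, 0, 10]]

    def test_region_tally_matches_per_read_oracle(self):
        rng = np.random.default_rng(11)
        t = make_transcript(strand="-", exons=((500, 1800),),
                            utr5=200, cds=900, utr3=200)
        ann = make_annotation(t)
        expected = {"utr5": 0, "cds": 0, "utr3": 0}
        rows = []
        for _ in range(20):
            m = int(rng.integers(0, t.mature_length))
            g = t.to_genomic_coord(m)
            rows.append(("chr1", g - 14, g + 16, "-"))
            expected[t.region_at(m)] += 1
        rc = count_by_region(make_reads(rows), ann)
        assert rc[["utr5", "cds", "utr3"]].iloc[0].to_dict() == expected

    def test_region_counts_sum_to_transcript_counts(self, small_sim):
        cm = count_per_transcript(small_sim["reads"], small_sim["ann"],
                                  assigned=small_sim["assigned"])
        rc = count_by_region(small_sim["reads"], small_sim["ann"],
                             assigned=small_sim["assigned"])
        per_tx = (rc.assign(total=rc[["utr5", "cds", "utr3"]].sum(axis=1))
                  .pivot(index="tx", columns="sample", values="total"))
        mrna_counts = cm.counts.loc[per_tx.index, per_tx.columns]
        pd.testing.assert_frame_equal(per_tx.fillna(0).astype(int), mrna_counts,
                                      check_names=False)


class TestCountsAndRpm:
    def test_library_size_equals_assigned_reads(self, small_sim):
        cm = count_per_transcript(small_sim["reads"], small_sim["ann"],
                                  assigned=small_sim["assigned"])
        per_sample = small_sim["assigned"].groupby("sample").size()
        for s in cm.counts.columns:
            assert cm.counts[s].sum() == cm.library_sizes[s] == per_sample[s]

    def test_rpm_arithmetic(self):
        t = make_transcript()
        ann = make_annotation(t)
        counts = pd.DataFrame({"s1": [5]}, index=pd.Index(["tx1"]))
        samples = pd.DataFrame({"role": ["crac_tagged"], "bio_rep": [1],
                                "tech_rep": [1], "library_size": [50_000]},
                               index=pd.Index(["s1"], name="sample"))
        cm = rpm_normalize(CountMatrix(counts=counts, samples=samples))
        assert cm.rpm.loc["tx1", "s1"] == pytest.approx(100.0)
        assert cm.counts.loc["tx1", "s1"] == 5  # raw preserved

    def test_rpm_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0]}, index=pd.Index(["tx1"]))
        samples = pd.DataFrame({"role": ["crac_tagged"], "bio_rep": [1],
                                "tech_rep": [1], "library_size": [0]},
                               index=pd.Index(["s1"], name="sample"))
        with pytest.raises(AssignmentError):
            rpm_normalize(CountMatrix(counts=counts, samples=samples))

    def test_rpm_column_conservation(self, small_sim):
        cm = small_sim["cm"]
        for s in cm.samples_with_role("crac_tagged"):
            assert cm.rpm[s].sum() == pytest.approx(1e6)
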