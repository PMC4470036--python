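import numpy as np
import pandas as pd
import pytest

from allelic_cna.annotation import chrom_slices
from allelic_cna.recurrence import (arm_alteration_table, mcr_permutation_test,
                                    probe_frequency, recurrent_amplifications)
from allelic_cna.segment import classify_scope

SEG_COLS = ["sample", "chrom", "start_index", "end_index", "start_bp",
            "end_bp", "n_probes", "mean_logR", "call"]


def _seg(sample, chrom, lo, hi, call, ann):
    pos = ann["pos"].to_numpy()
    return (sample, chrom, lo, hi, int(pos[lo]), int(pos[hi - 1]) + 1,
            hi - lo, float(call) * 0.5, call)


def _cohort_segments(ann, layout):
    """layout: list of (sample, chrom, lo, hi, call) probe-index runs; the
    rest of each genome is filled with neutral segments."""
    rows = []
    sls = chrom_slices(ann)
    samples = sorted({s for s, *_ in layout})
    for s in samples:
        for chrom, sl in sls.items():
            cuts = sorted({lo for s2, c, lo, hi, _ in layout
                           if s2 == s and c == chrom}
                          | {hi for s2, c, lo, hi, _ in layout
                             if s2 == s and c == chrom}
                          | {sl.start, sl.stop})
            for lo, hi in zip(cuts, cuts[1:]):
                call = next((k for s2, c, l, h, k in layout
                             if s2 == s and c == chrom and l <= lo and hi <= h),
                            0)
                rows.append(_seg(s, chrom, lo, hi, call, ann))
    return pd.DataFrame(rows, columns=SEG_COLS)


class TestProbeFrequency:
    def test_all_neutral(self):
        assert (probe_frequency(np.zeros((10, 4), dtype=int), "gain") == 0).all()

    def test_fraction(self):
        calls = np.zeros((1, 20), dtype=int)
        calls[0, :12] = 1
        assert probe_frequency(calls, "gain")[0] == pytest.approx(0.6)

    def test_amplification_counts_as_gain(self):
        calls = np.array([[2, 1, 0, 0]])
        assert probe_frequency(calls, "gain")[0] == pytest.approx(0.5)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            probe_frequency(np.zeros((1, 1), dtype=int), "sideways")


class TestMCR:
    def test_shared_event_yields_overlapping_mcr(self, genome_annotation):
        ann = genome_annotation
        sls = chrom_slices(ann)
        lo = sls["8"].start + 40
        layout = [(f"S{i}", "8", lo, lo + 30, 1) for i in range(12)]
        # spread some unrelated private gains elsewhere
        layout += [(f"S{i}", str(1 + i), 10 + 3 * i, 80 + 3 * i, 1)
                   for i in range(12, 20)]
        segs = _cohort_segments(ann, layout)
        mcrs = mcr_permutation_test(segs, ann, "gain", n_perm=300, seed=0)
        hit = mcrs[(mcrs["chrom"] == "8")
                   & (mcrs["start_bp"] < ann["pos"].iloc[lo + 30])
                   & (mcrs["end_bp"] > ann["pos"].iloc[lo])]
        assert len(hit) >= 1
        assert (hit["frequency"] >= 12 / 20).all()

    def test_no_altered_segments_empty(self, genome_annotation):
        segs = _cohort_segments(genome_annotation,
                                [("S0", "1", 0, 1, 0), ("S1", "1", 0, 1, 0)])
        out = mcr_permutation_test(segs, genome_annotation, "loss",
                                   n_perm=100, seed=0)
        assert out.empty

    def test_single_sample_cohort_does_not_crash(self, genome_annotation):
        segs = _cohort_segments(genome_annotation, [("S0", "2", 5, 60, 1)])
        out = mcr_permutation_test(segs, genome_annotation, "gain",
                                   n_perm=100, seed=0)
        assert isinstance(out, pd.DataFrame)

    def test_sample_order_invariance(self, genome_annotation):
        ann = genome_annotation
        layout = [(f"S{i}", "3", 100, 160, -1) for i in range(8)]
        layout += [(f"S{i}", "5", 30 + i, 90 + i, -1) for i in range(8, 12)]
        segs = _cohort_segments(ann, layout)
        shuffled = segs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = mcr_permutation_test(segs, ann, "loss", n_perm=200, seed=3)
        b = mcr_permutation_test(shuffled, ann, "loss", n_perm=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_region_frequency_bounded_by_members(self, genome_annotation):
        ann = genome_annotation
        layout = [(f"S{i}", "4", 50, 120, 1) for i in range(10)]
        segs = _cohort_segments(ann, layout)
        mcrs = mcr_permutation_test(segs, ann, "gain", n_perm=200, seed=1)
        for r in mcrs.itertuples():
            assert 0 < r.frequency <= 1

    def test_seed_stability_at_high_n_perm(self, genome_annotation):
        ann = genome_annotation
        layout = [(f"S{i}", "6", 70, 130, 1) for i in range(9)]
        layout += [(f"S{i}", "7", 10, 200, 1) for i in range(9, 12)]
        segs = _cohort_segments(ann, layout)
        a = mcr_permutation_test(segs, ann, "gain", n_perm=2000, seed=11)
        b = mcr_permutation_test(segs, ann, "gain", n_perm=2000, seed=12)
        # p-values stabilize with many permutations: same regions either way
        assert a[["chrom", "start_bp", "end_bp"]].equals(
            b[["chrom", "start_bp", "end_bp"]])
        if len(a):
            assert np.allclose(a["p_adjusted"], b["p_adjusted"], atol=0.01)


class TestRecurrentAmplifications:
    def test_no_amplifications_empty(self, genome_annotation):
        segs = _cohort_segments(genome_annotation, [("S0", "1", 0, 50, 1),
                                                    ("S1", "1", 0, 50, 1)])
        assert recurrent_amplifications(segs, genome_annotation).empty

    def test_shared_amplicon_in_three_samples(self, genome_annotation):
        layout = [(f"S{i}", "2", 100, 140, 2) for i in range(3)]
        layout += [(f"S{i}", "2", 0, 1, 0) for i in range(3, 10)]
        segs = _cohort_segments(genome_annotation, layout)
        out = recurrent_amplifications(segs, genome_annotation, min_samples=3)
        assert len(out) == 1
        assert out.iloc[0]["max_samples"] == 3
        assert set(out.iloc[0]["samples"].split(",")) == {"S0", "S1", "S2"}

    def test_below_threshold_empty(self, genome_annotation):
        layout = [(f"S{i}", "2", 100, 140, 2) for i in range(2)]
        segs = _cohort_segments(genome_annotation, layout)
        out = recurrent_amplifications(segs, genome_annotation, min_samples=3)
        assert out.empty


class TestArmAlterationTable:
    def test_whole_chromosome_does_not_double_count_arms(
            self, genome_annotation):
        ann = genome_annotation
        sls = chrom_slices(ann)
        layout = [(f"S{i}", "4", sls["4"].start, sls["4"].stop, -1)
                  for i in range(5)]
        segs = classify_scope(_cohort_segments(ann, layout), ann)
        table = arm_alteration_table(segs)
        assert table.loc["4", "whole_loss"] == 5
        assert table.loc["4", "p_loss"] == 0 and table.loc["4", "q_loss"] == 0

    def test_single_arm_gain(self, genome_annotation):
        ann = genome_annotation
        from allelic_cna.annotation import arm_index_ranges
        sl = arm_index_ranges(ann)[("5", "p")]
        segs = classify_scope(
            _cohort_segments(ann, [("S0", "5", sl.start, sl.stop, 1),
                                   ("S1", "1", 0, 1, 0)]), ann)
        table = arm_alteration_table(segs)
        assert table.loc["5", "p_gain"] == 1
        assert table.loc["5", "whole_gain"] == 0
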