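import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from allelic_cna.curated import CuratedLineTable
from allelic_cna.evaluation import chi2_hand_formula, ranksum_exact_oracle
from allelic_cna.instability import (cohort_instability, count_dual_mutants,
                                     count_gene_loss, frequency_chi2,
                                     group_association, instability_metrics,
                                     replicate_concordance, tertile_classify)

SEG_COLS = ["sample", "chrom", "start_index", "end_index", "start_bp",
            "end_bp", "n_probes", "mean_logR", "call"]


def _segments(rows):
    return pd.DataFrame(rows, columns=SEG_COLS)


class TestInstabilityMetrics:
    def test_fully_neutral_genome(self):
        segs = _segments([("s", "1", 0, 1000, 0, 100_000_000, 1000, 0.0, 0)])
        m = instability_metrics(segs, 1000)
        assert (m["mb_gained"], m["mb_lost"], m["mb_altered"],
                m["frac_probes_altered"], m["n_altered_segments"]) == \
            (0, 0, 0, 0.0, 0)

    def test_single_gained_segment(self):
        segs = _segments([
            ("s", "1", 0, 100, 0, 10_000_000, 100, 0.58, 1),
            ("s", "1", 100, 1000, 10_000_000, 100_000_000, 900, 0.0, 0),
        ])
        m = instability_metrics(segs, 1000)
        assert m["mb_gained"] == pytest.approx(10.0)
        assert m["frac_probes_altered"] == pytest.approx(0.1)
        assert m["n_altered_segments"] == 1
        assert m["mb_altered"] == m["mb_gained"] + m["mb_lost"]

    def test_additive_over_chromosomes(self):
        per_chrom = [
            _segments([("s", "1", 0, 50, 0, 5_000_000, 50, -0.6, -1)]),
            _segments([("s", "2", 50, 90, 0, 4_000_000, 40, 0.6, 1)]),
        ]
        combined = pd.concat(per_chrom, ignore_index=True)
        total = instability_metrics(combined, 90)
        parts = [instability_metrics(p, 90) for p in per_chrom]
        for key in ("mb_gained", "mb_lost", "mb_altered",
                    "frac_probes_altered", "n_altered_segments"):
            assert total[key] == pytest.approx(sum(p[key] for p in parts))

    def test_cohort_profile_includes_tertiles(self):
        rows = []
        for i, n_alt in enumerate((10, 100, 400)):
            rows.append((f"s{i}", "1", 0, n_alt, 0, n_alt * 100_000, n_alt,
                         0.6, 1))
            rows.append((f"s{i}", "1", n_alt, 1000, n_alt * 100_000,
                         100_000_000, 1000 - n_alt, 0.0, 0))
        prof = cohort_instability(_segments(rows), 1000)
        assert list(prof["mb_altered_tertile"]) == ["low", "intermediate",
                                                    "high"]


class TestTertiles:
    def test_one_to_nine(self):
        labels = tertile_classify(np.arange(1, 10))
        assert list(labels) == ["low"] * 3 + ["intermediate"] * 3 + ["high"] * 3

    def test_all_equal_all_low_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = tertile_classify(np.full(6, 2.0))
        assert (labels == "low").all()

    def test_order_invariance_and_balance(self, rng):
        values = rng.normal(size=30)
        labels = tertile_classify(values)
        perm = rng.permutation(30)
        assert (tertile_classify(values[perm]) == labels[perm]).all()
        counts = pd.Series(labels).value_counts()
        assert all(abs(c - 10) <= 1 for c in counts)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            tertile_classify(np.array([1.0, 2.0]))


class TestGroupAssociation:
    def test_identical_groups_p_one(self):
        values = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        p, means, _ = group_association(values, groups)
        assert p == pytest.approx(1.0)
        assert means[0] == means[1]

    def test_extreme_separation_three_vs_three(self):
        values = np.array([1.0, 2, 3, 10, 11, 12])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        p, _, _ = group_association(values, groups)
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3) ... smallest attainable

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n1=st.integers(2, 8), n2=st.integers(2, 8),
           seed=st.integers(0, 10**6))
    def test_exact_path_matches_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        p, _, _ = group_association(vals,
                                    np.array(["a"] * n1 + ["b"] * n2))
        assert p == pytest.approx(ranksum_exact_oracle(vals[:n1], vals[n1:]),
                                  abs=1e-12)

    def test_separated_cohorts_significant(self, rng):
        low = rng.normal(1000, 400, 12)    # stable-genome-like group
        high = rng.normal(1800, 350, 12)   # unstable-genome-like group
        p, _, _ = group_association(np.concatenate([low, high]),
                                    np.array(["wt"] * 12 + ["mut"] * 12))
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_association(np.array([1.0, 2.0]), np.array(["a", "a"]))


class TestFrequencyChi2:
    def test_identical_proportions(self):
        stat, p = frequency_chi2(5, 50, 10, 100)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        stat, _ = frequency_chi2(10, 50, 46, 100)
        assert stat == pytest.approx(
            chi2_hand_formula([[10, 40], [46, 54]]), abs=1e-9)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning, match="margin"):
            stat, p = frequency_chi2(0, 10, 0, 20)
        assert stat == 0.0 and p == 1.0

    def test_yates_reduces_statistic(self):
        plain, _ = frequency_chi2(10, 50, 46, 100)
        corrected, _ = frequency_chi2(10, 50, 46, 100, yates=True)
        assert corrected < plain


class TestReplicateConcordance:
    def test_identical(self):
        rate, breakdown = replicate_concordance(np.zeros(10), np.zeros(10))
        assert rate == 1.0 and breakdown == {}

    def test_breakdown_types(self):
        a = np.array([1, -1] + [0] * 8)
        b = np.zeros(10, dtype=int)
        rate, breakdown = replicate_concordance(a, b)
        assert rate == pytest.approx(0.8)
        assert breakdown == {"gain/no-change": pytest.approx(0.1),
                             "loss/no-change": pytest.approx(0.1)}

    def test_duplicate_simulations_concordant(self, small_annotation, config):
        from allelic_cna.model import CNEvent, EventPlan, NoiseModel
        from allelic_cna.segment import calls_by_probe, segment_sample
        from allelic_cna.simulate import simulate_sample
        plan = EventPlan("r", (CNEvent("1", 5_000_000, 20_000_000, 3, 1),
                               CNEvent("2", 10_000_000, 18_000_000, 1, 0)))
        calls = []
        for seed in (100, 101):
            sig, _ = simulate_sample(plan, small_annotation, NoiseModel(),
                                     seed=seed)
            segs = segment_sample(sig, small_annotation, config, sample="r",
                                  seed=seed)
            mat, _ = calls_by_probe(segs, len(small_annotation))
            calls.append(mat[:, 0])
        rate, _ = replicate_concordance(calls[0], calls[1])
        assert rate > 0.95


def _toy_table(rows):
    cols = ["name", "source", "grade", "sex"]
    genes = ["FGFR3", "PIK3CA", "INK4A"]
    for g in genes:
        cols += [f"{g}_mut", f"{g}_cn"]
    cols += ["instability_group"]
    return CuratedLineTable(pd.DataFrame(rows, columns=cols))


class TestCuratedCounts:
    def test_empty_table(self):
        table = _toy_table([])
        assert count_dual_mutants(table, "FGFR3", "PIK3CA") == 0

    def test_dual_mutant_counting(self):
        table = _toy_table([
            ("L1", ".", ".", "M", "S249C:1", ".", "E545K:4", ".", ".", ".", "."),
            ("L2", ".", ".", "M", "S249C:1", ".", "WT:4", ".", ".", ".", "."),
        ])
        assert count_dual_mutants(table, "FGFR3", "PIK3CA") == 1

    def test_fusion_and_amp_not_point_mutations(self):
        table = _toy_table([
            ("L1", ".", ".", "M", "WT:1;FGFR3-TACC3_fusion:13", "Amp:4",
             "E545K:4", ".", ".", ".", "."),
        ])
        assert count_dual_mutants(table, "FGFR3", "PIK3CA") == 0

    def test_own_data_precedence_for_loss(self):
        table = _toy_table([
            ("L1", ".", ".", "M", ".", ".", ".", ".", ".", "HD:1;WT:4", "."),
            ("L2", ".", ".", "M", ".", ".", ".", ".", ".", "HD:6", "."),
        ])
        assert count_gene_loss(table, "INK4A", "HD",
                               policy="own_data_precedence") == 1
        assert count_gene_loss(table, "INK4A", "HD", policy="any_source") == 2

    def test_single_hd_line(self):
        table = _toy_table([
            ("L1", ".", ".", "M", ".", ".", ".", ".", ".", "HD:4", "."),
            ("L2", ".", ".", "M", ".", ".", ".", ".", ".", "WT:4", "."),
        ])
        assert count_gene_loss(table, "INK4A", "HD") == 1
        assert count_gene_loss(table, "INK4A", "LOH") == 0
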