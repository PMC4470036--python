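import numpy as np
import pandas as pd
import pytest

from allelic_cna.allelic import (call_allelic_state, classify_upd, detect_upd,
                                 gene_status, upd_summary)
from allelic_cna.model import CNEvent, EventPlan, NoiseModel, RunConfig
from allelic_cna.segment import segment_sample
from allelic_cna.simulate import simulate_sample

UPD_COLS = ["sample", "chrom", "start_bp", "end_bp", "start_index",
            "end_index", "n_probes", "mean_logR"]


def _signals(ann, genotype, baf, logR):
    return pd.DataFrame({"probe_id": ann["probe_id"].to_numpy()[:len(baf)],
                         "logR": logR, "baf": baf, "genotype": genotype})


class TestAllelicState:
    @pytest.mark.parametrize("gt,baf,seg_mean,expected", [
        ("AA", 0.01, -0.4, "LOH"),
        ("NC", 0.37, -2.5, "HD"),
        ("AB", 0.50, 0.0, "normal"),
        ("AA", 0.01, 0.0, "normal"),   # no LogR decline: not LOH
        ("NC", 0.02, -2.5, "normal"),  # BAF near 0 is not abnormal
        ("BB", 0.99, -0.2, "LOH"),
    ])
    def test_rules(self, small_annotation, gt, baf, seg_mean, expected):
        sig = _signals(small_annotation, np.array([gt], dtype=object),
                       np.array([baf]), np.array([seg_mean]))
        segs = pd.DataFrame([{"sample": "s", "chrom": "1", "start_index": 0,
                              "end_index": 1, "start_bp": 0, "end_bp": 1,
                              "n_probes": 1, "mean_logR": seg_mean,
                              "call": 0}])
        state = call_allelic_state(sig, segs, small_annotation.head(1))
        assert state[0] == expected


class TestDetectUPD:
    def test_planted_copy_neutral_loh_found(self, small_annotation, config):
        ev = CNEvent("1", 15_000_000, 25_000_000, 2, 0)
        sig, _ = simulate_sample(EventPlan("u", (ev,)), small_annotation,
                                 NoiseModel(), seed=9)
        found = detect_upd(sig, small_annotation, config, sample="u")
        assert len(found) == 1
        r = found.iloc[0]
        ov = min(r["end_bp"], ev.end) - max(r["start_bp"], ev.start)
        assert min(ov / (ev.end - ev.start),
                   ov / (r["end_bp"] - r["start_bp"])) >= 0.9

    def test_diploid_chromosome_yields_nothing(self, small_annotation, config):
        sig, _ = simulate_sample(EventPlan("n"), small_annotation,
                                 NoiseModel(), seed=10)
        assert detect_upd(sig, small_annotation, config, sample="n").empty

    def test_hemizygous_deletion_not_upd(self, small_annotation, config):
        ev = CNEvent("2", 10_000_000, 25_000_000, 1, 0)
        sig, _ = simulate_sample(EventPlan("d", (ev,)), small_annotation,
                                 NoiseModel(), seed=11)
        assert detect_upd(sig, small_annotation, config, sample="d").empty

    def test_events_respect_logr_band(self, small_annotation, config):
        ev = CNEvent("1", 0, 45_000_000, 2, 0)
        sig, _ = simulate_sample(EventPlan("u", (ev,)), small_annotation,
                                 NoiseModel(), seed=12)
        found = detect_upd(sig, small_annotation, config, sample="u")
        assert (found["mean_logR"] >= -config.upd_logR_zero_tol).all()

    def test_window_clamped_with_warning(self, config, caplog):
        from allelic_cna.annotation import make_annotation
        ann = make_annotation(n_probes=30, chrom_sizes_mb={"1": 1})
        sig, _ = simulate_sample(EventPlan("w"), ann, NoiseModel(), seed=0)
        with caplog.at_level("WARNING", logger="allelic_cna"):
            detect_upd(sig, ann, config, sample="w")
        assert any("clamped" in r.message for r in caplog.records)


class TestClassifyUPD:
    def _run(self, ann, events, seed, config):
        sig, _ = simulate_sample(EventPlan("c", tuple(events)), ann,
                                 NoiseModel(), seed=seed)
        segs = segment_sample(sig, ann, config, sample="c", seed=seed)
        found = detect_upd(sig, ann, config, sample="c")
        return classify_upd(found, segs, ann, config)

    def test_whole_chromosome_neutral_is_category_1(self, small_annotation,
                                                    config):
        out = self._run(small_annotation,
                        [CNEvent("1", 0, 45_000_000, 2, 0)], 21, config)
        assert list(out["category"]) == [1]

    def test_whole_arm_is_category_2(self, small_annotation, config):
        out = self._run(small_annotation,
                        [CNEvent("1", 0, 18_000_000, 2, 0)], 22, config)
        assert list(out["category"]) == [2]

    def test_focal_neutral_is_category_3(self, small_annotation, config):
        out = self._run(small_annotation,
                        [CNEvent("1", 20_000_000, 28_000_000, 2, 0)], 23,
                        config)
        assert list(out["category"]) == [3]

    def test_focal_duplication_is_category_4(self, small_annotation, config):
        out = self._run(small_annotation,
                        [CNEvent("1", 20_000_000, 30_000_000, 3, 0)], 24,
                        config)
        assert list(out["category"]) == [4]

    def test_amplified_upd_is_category_5(self, small_annotation, config):
        out = self._run(small_annotation,
                        [CNEvent("1", 20_000_000, 30_000_000, 6, 0)], 25,
                        config)
        assert list(out["category"]) == [5]

    def test_near_whole_with_focal_deletion_is_category_6(
            self, small_annotation, config):
        out = self._run(small_annotation,
                        [CNEvent("1", 0, 39_000_000, 2, 0),
                         CNEvent("1", 39_000_000, 45_000_000, 1, 0)], 26,
                        config)
        assert list(out["category"]) == [6]


class TestGeneStatus:
    def _ann_states(self, small_annotation):
        states = np.full(len(small_annotation), "normal", dtype=object)
        return states

    def test_all_loh_probes(self, small_annotation):
        states = self._ann_states(small_annotation)
        probes = small_annotation["probe_id"].iloc[:10].tolist()
        states[:10] = "LOH"
        segs = pd.DataFrame(columns=["start_index", "end_index", "call"])
        out = gene_status({"G": probes}, states, segs, small_annotation)
        assert out.iloc[0]["status"] == "LOH"

    def test_single_hd_probe_falls_through_to_segment_call(
            self, small_annotation):
        states = self._ann_states(small_annotation)
        states[0] = "HD"
        probes = small_annotation["probe_id"].iloc[:4].tolist()
        segs = pd.DataFrame([{"start_index": 0, "end_index": 4, "call": 1}])
        out = gene_status({"G": probes}, states, segs, small_annotation,
                          min_probe_support=2)
        assert out.iloc[0]["status"] == "gain"

    def test_unmapped_gene_missing_with_warning(self, small_annotation,
                                                caplog):
        states = self._ann_states(small_annotation)
        segs = pd.DataFrame(columns=["start_index", "end_index", "call"])
        with caplog.at_level("WARNING", logger="allelic_cna"):
            out = gene_status({"G": ["nope"]}, states, segs, small_annotation)
        assert out.iloc[0]["status"] is None

    def test_planted_hd_gene(self, small_annotation, config):
        ev = CNEvent("2", 20_000_000, 22_000_000, 0, 0)
        sig, _ = simulate_sample(EventPlan("h", (ev,)), small_annotation,
                                 NoiseModel(), seed=30)
        segs = segment_sample(sig, small_annotation, config, sample="h",
                              seed=30)
        states = call_allelic_state(sig, segs, small_annotation, config)
        ann = small_annotation
        probes = ann["probe_id"][(ann["chrom"] == "2")
                                 & (ann["pos"] >= ev.start)
                                 & (ann["pos"] < ev.end)].iloc[:22].tolist()
        out = gene_status({"G": probes}, states, segs, small_annotation)
        assert out.iloc[0]["status"] == "HD"


class TestUpdSummary:
    def test_empty(self):
        events = pd.DataFrame(columns=UPD_COLS)
        table, median = upd_summary(events, ["a", "b"])
        assert table["n_events"].tolist() == [0, 0] and median == 0

    def test_median_of_counts(self):
        rows = ([("a", "1", 0, 10, 0, 1, 1, 0.0)] * 3
                + [("b", "1", 0, 10, 0, 1, 1, 0.0)] * 5)
        events = pd.DataFrame(rows, columns=UPD_COLS)
        table, median = upd_summary(events, ["a", "b"])
        assert sorted(table["n_events"]) == [3, 5]
        assert median == 4
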