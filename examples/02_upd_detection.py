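"""Detect and classify uniparental disomy (copy-neutral LOH).

One chromosome carries whole-chromosome UPD (category 1), the other a focal
10-Mb UPD (category 3): LogR stays near 0 but heterozygous genotypes vanish
over the event. The detector reports each run with its mean LogR and the
six-category classification.
"""
import allelic_cna as ac
from allelic_cna.model import CNEvent, EventPlan, NoiseModel

ann = ac.make_annotation(n_probes=3600, chrom_sizes_mb={"1": 45, "2": 45})
plan = EventPlan("demo", (
    CNEvent("1", 0, 45_000_000, 2, 0),            # whole-chromosome UPD
    CNEvent("2", 18_000_000, 28_000_000, 2, 0),   # focal UPD
))
signals, truth = ac.simulate_sample(plan, ann, NoiseModel(), seed=7)
segments = ac.segment_sample(signals, ann, sample="demo", seed=7)
events = ac.detect_upd(signals, ann, sample="demo")
events = ac.classify_upd(events, segments, ann)

print("UPD events (category 1 = whole chromosome, 3 = focal):")
cols = ["chrom", "start_bp", "end_bp", "n_probes", "mean_logR",
        "category", "category_label"]
print(events[cols].round(3).to_string(index=False))

summary, median = ac.upd_summary(events, ["demo"])
print(f"\nevents per sample: {summary['n_events'].tolist()}, "
      f"cohort median {median:.0f}")
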