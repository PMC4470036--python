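"""Simulate one tumor sample with planted copy-number events, segment its
LogR profile and print the categorical calls.

Two 45-Mb chromosomes carry a 3-copy gain, a hemizygous deletion and a
6-copy amplification; the segment table should recover their boundaries and
call them +1 / -1 / +2 (amplification = >= 5 copies), with everything else
neutral (0).
"""
import allelic_cna as ac
from allelic_cna.model import CNEvent, EventPlan, NoiseModel

ann = ac.make_annotation(n_probes=3600, chrom_sizes_mb={"1": 45, "2": 45})
plan = EventPlan("demo", (
    CNEvent("1", 5_000_000, 15_000_000, 3, 1),    # single-copy gain
    CNEvent("1", 30_000_000, 38_000_000, 1, 0),   # hemizygous loss
    CNEvent("2", 20_000_000, 24_000_000, 6, 1),   # amplification
))
signals, truth = ac.simulate_sample(plan, ann, NoiseModel(), seed=42)
segments = ac.segment_sample(signals, ann, sample="demo", seed=42)

print("planted truth:")
print(truth.to_string(index=False))
print("\nrecovered segments (call: -1 loss, 0 neutral, +1 gain, +2 amp):")
cols = ["chrom", "start_bp", "end_bp", "n_probes", "mean_logR", "call"]
print(segments[cols].round(3).to_string(index=False))
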