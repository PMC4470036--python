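"""Genomic-instability scoring and the curated cell-line table.

Simulates a small cohort with very different alteration burdens, computes
the three instability metrics (Mb altered, fraction of probes altered,
number of altered segments) with cohort tertiles, then queries the packaged
curated table of 49 bladder-cancer cell lines: dual FGFR3+PIK3CA point
mutants and INK4A losses under own-data precedence.
"""
import allelic_cna as ac
from allelic_cna.model import CNEvent, EventPlan, NoiseModel

ann = ac.make_annotation(n_probes=4000, include_x=False)
plans = {
    "quiet":    (),
    "moderate": (CNEvent("3", 0, 80_000_000, 1, 0),),
    "unstable": (CNEvent("1", 0, 200_000_000, 3, 1),
                 CNEvent("4", 0, 150_000_000, 1, 0),
                 CNEvent("8", 20_000_000, 120_000_000, 1, 0)),
}
cohort = {}
for i, (name, events) in enumerate(plans.items()):
    sig, _ = ac.simulate_sample(EventPlan(name, events), ann, NoiseModel(),
                                seed=100 + i)
    cohort[name] = sig
segments = ac.segment_cohort(cohort, ann, seed=5)
profiles = ac.cohort_instability(segments, len(ann))
cols = ["sample", "mb_gained", "mb_lost", "mb_altered",
        "frac_probes_altered", "n_altered_segments", "mb_altered_tertile"]
print(profiles[cols].round(3).to_string(index=False))

table = ac.load_table1_fixture()
dual = ac.count_dual_mutants(table, "FGFR3", "PIK3CA", policy="any_source")
hd = ac.count_gene_loss(table, "INK4A", "HD", policy="own_data_precedence")
loh = ac.count_gene_loss(table, "INK4A", "LOH", policy="own_data_precedence")
print(f"\ncurated table ({len(table)} lines): "
      f"{dual} lines mutant in both FGFR3 and PIK3CA; "
      f"INK4A homozygously deleted in {hd}, LOH in {loh}")
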