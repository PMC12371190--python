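"""Call differentially methylated regions (DMRs) between FCD IIb and IIa.

A synthetic cohort is generated with 15 planted IIb-specific effects of
|log2 fold change| = 2; the negative-binomial GLM with spike/library
offsets tests each region by likelihood ratio.  The output compares the
number of DMRs called at p < 0.01 with the planted truth and shows the
direction split (increased vs reduced methylation).
"""

from mbdmethyl import ContrastSpec, run_all_contrasts
from mbdmethyl.simulate import SimulationConfig, simulate_cohort, simulate_counts

cfg = SimulationConfig(
    seed=7,
    n_regions=300,
    n_dmr_per_contrast=15,
    dmr_log2_effect=2.0,
    dispersion=0.1,
    paired_fraction=0.0,
    n_marker_regions=0,
    n_subjects_per_group={"IIa": 8, "IIb": 8},
    dmr_classes=(("IIb_only", {"IIb": 1.0}),),
)
samples = simulate_cohort(cfg)
cohort = simulate_counts(samples, cfg)

contrast = ContrastSpec("IIb_vs_IIa", frozenset({"IIb"}), frozenset({"IIa"}))
table, counts = run_all_contrasts(cohort.counts, samples, [contrast], tissue_mode="brain")

sig = table[table["p_value"] < 0.01]
truth = cohort.truth.set_index("region_id")
hits = truth.loc[sig["region_id"], "label"].eq("IIb_only").sum()
print(counts.to_string(index=False))
print(f"DMRs at p<0.01: {len(sig)} ({hits} of {15} planted effects recovered)")
print(f"median |log2FC| among detected: {sig['log2fc'].abs().median():.2f} (injected 2.0)")
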