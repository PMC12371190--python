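"""Parse the packaged discovery cohort and summarise its design.

The discovery cohort is 21 surgical-epilepsy subjects (13 focal cortical
dysplasia across subtypes Ia/IIa/IIb/IIIa/IIId, 8 other pathologies), each
with a matched blood sample in the original study.  The printed counts are
the group sizes every downstream contrast is built from.
"""

from mbdmethyl import cohort_summary, load_discovery_cohort, load_replication_cohort

records = load_discovery_cohort()
s = cohort_summary(records)
print(f"discovery samples: {s.n_samples} (FCD {s.n_fcd}, other pathologies {s.n_other})")
print("per classification:", {k: v for k, v in s.per_classification.items() if v})

r = cohort_summary(load_replication_cohort())
print(
    f"replication cohort: {r.n_samples} samples, {r.n_paired} paired subjects, "
    f"{r.n_unpaired_brain} unpaired brain, {r.n_unpaired_blood} unpaired blood"
)
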