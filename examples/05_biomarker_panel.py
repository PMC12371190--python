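"""Select a subtype biomarker panel by three-contrast intersection.

A cohort is simulated with IIa-only, IIb-only and shared (graded) planted
effects; DMRs passing p < 0.01, AUC > 0.65 and > 4 CpG in each of the
contrasts IIa-vs-others, IIb-vs-others and IIb-vs-IIa are intersected:
IIa-defining = (A & C) - B, IIb-defining = (B & C) - A, plus the single
top-AUC region found in all three.  The class labels are checked against
the generative truth.
"""

from mbdmethyl.benchmarks import panel_logic_agreement

res = panel_logic_agreement(seed=3)
print(f"panel members: {res['n_members']} "
      f"({res['n_iia_defining']} IIa-defining, {res['n_iib_defining']} IIb-defining, "
      f"{res['n_top']} top IIb-vs-IIa)")
print(f"planted per class: {res['n_planted_per_class']}")
print(f"class labels match generative truth: {res['all_match']} "
      f"(fraction {res['match_fraction']:.2f})")
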