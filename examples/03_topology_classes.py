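"""Rule-based topology classification of single neurons.

Classifies the demo scenario's neurons into the S/P/C/M/T/H/D topology
classes from their arbor-domain geometry relative to the brain midline, and
compares against the generator's planted classes.
"""

from hemimorph import classification_report, demo_scenario

scenario = demo_scenario(seed=1)
skeletons = scenario.skeletons()
report = classification_report(skeletons, scenario.brain)
truth = scenario.true_classes()

print(report.to_string(index=False))
hits = sum(row["class"] == truth[row.type_name] for _, row in report.iterrows())
print(f"\nrecovered planted class for {hits}/{len(report)} neurons")
# S: one unilateral domain; P: several, one hemisphere; C: one domain on the
# midline; M: midline plus lateral domains; T/H: midline crossing without /
# with mirrored innervation; D: arbors leaving the brain volume.
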