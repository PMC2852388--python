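"""EC-number comparison of reaction content across reconstructions.

Metabolite naming conventions differ between models, so reaction
content is compared through Enzyme Commission numbers, with the
multi-EC reconciliation rule applied before partitioning.
"""

from thermoflux import EcAnnotation, compare_models, extract_ec_set, pathway_frequency

# toy annotation sets for three organisms; R2 carries two ECs
cth_annotations = [
    EcAnnotation("R1", ["2.7.1.40"]),          # pyruvate kinase
    EcAnnotation("R2", ["1.12.7.2", "1.1.1.1"]),  # Fd hydrogenase + a sibling EC
    EcAnnotation("R3", ["3.2.1.4"]),           # cellulase
]
cac_set = {"2.7.1.40", "1.1.1.1", "2.3.1.54"}
sce_set = {"2.7.1.40", "1.1.1.1", "1.1.1.2"}

cth_set = extract_ec_set(cth_annotations, reference_sets=[cac_set, sce_set])
print(f"Cth EC set after reconciliation: {sorted(cth_set)}")
print("-> 1.12.7.2 was dropped: its sibling EC 1.1.1.1 on the same reaction")
print("   already occurs in the reference models, so the reaction is shared.")

result = compare_models({"Cth": cth_set, "Cac": cac_set, "Sce": sce_set})
print()
for label, count in result.counts().items():
    print(f"  {label}: {count}")

ec2path = {
    "3.2.1.4": ["Starch and Sucrose Metabolism"],
    "2.7.1.40": ["Glycolysis"],
    "1.1.1.1": ["Glycolysis", "Fatty acid degradation"],
}
print()
print("pathways of the Cth-exclusive ECs:")
print(pathway_frequency(result.exclusive["Cth"], ec2path).to_string(index=False))
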