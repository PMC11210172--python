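"""Which diagnostic variants can serve as MRD markers?

Builds a handful of myeloid-panel variants and runs them through the
default eligibility policy (CHIP and pan-myeloid-neoplasia genes excluded,
VUS excluded, everything else tracked) and the strict preset.
"""

from liqbio import EligibilityPolicy, MarkerVariant, classify_marker_eligibility

variants = [
    MarkerVariant("P1", "ETV6", "p.R418M", "chr12", 100, "G", "T",
                  variant_class="missense"),
    MarkerVariant("P1", "DNMT3A", "p.Arg882His", "chr2", 200, "C", "T",
                  variant_class="missense"),
    MarkerVariant("P2", "JAK2", "p.V617F", "chr9", 300, "G", "T",
                  variant_class="missense"),
    MarkerVariant("P2", "TP53", "p.C275Y", "chr17", 400, "G", "A",
                  variant_class="missense"),
    MarkerVariant("P3", "NPM1", "p.W288fs", "chr5", 500, "C", "CTCTG",
                  variant_class="frameshift"),
    MarkerVariant("P3", "WT1", "p.K459fs", "chr11", 600, "AG", "A",
                  variant_class="frameshift", pathogenicity="VUS"),
]

for policy_name, policy in [("default", EligibilityPolicy()),
                            ("strict", EligibilityPolicy.hasserjian_strict())]:
    print(f"policy: {policy_name}")
    for v in variants:
        decision = classify_marker_eligibility(v, policy)
        verdict = "eligible" if decision else f"excluded ({decision.reason})"
        print(f"  {v.gene:7s} {v.hgvs_p:13s} -> {verdict}")

# An "excluded" verdict means the variant may persist in non-leukemic
# clones (age-related clonal hematopoiesis, preleukemic states) and would
# overcall residual disease; eligible variants track the leukemic clone.
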