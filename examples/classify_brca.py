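"""Classify BRCA1/2 status from variant and copy-number evidence.

Three samples illustrate the three-way classification: biallelic hits
(deficient), a single pathogenic allele (monoallelic pathogenic), and a
VUS-only sample (intact).
"""

from hrdscar import GeneCopyNumberCall, VariantCall, classify_brca_status, gene_cna_call

cases = {
    "biallelic": dict(
        variants=[
            VariantCall("biallelic", "BRCA1", "frameshift", "unknown", "germline", "a1"),
            VariantCall("biallelic", "BRCA1", "nonsense", "pathogenic", "somatic", "a2"),
        ],
        cnas=[],
    ),
    "single_hit_plus_deletion": dict(
        variants=[VariantCall("single_hit_plus_deletion", "BRCA2", "nonsense", "unknown", "somatic", "a1")],
        cnas=[GeneCopyNumberCall("single_hit_plus_deletion", "BRCA2", -1.4, gene_cna_call(-1.4))],
    ),
    "monoallelic": dict(
        variants=[VariantCall("monoallelic", "BRCA2", "missense", "likely_pathogenic", "germline", "a1")],
        cnas=[],
    ),
    "vus_only": dict(
        variants=[VariantCall("vus_only", "BRCA1", "missense", "vus", "somatic", "a1")],
        cnas=[],
    ),
}

for name, evidence in cases.items():
    status = classify_brca_status(evidence["variants"], evidence["cnas"], sample_id=name)
    print(f"{name:26s} -> {status.status}")
    for line in status.evidence:
        print(f"{'':28s}{line}")
# Deficient requires a second hit (biallelic variants, variant + deletion,
# homozygous deletion, or rearrangement); a lone pathogenic allele is
# monoallelic; anything less leaves the gene intact.
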