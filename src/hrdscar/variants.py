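"""BRCA1/2 status and HRR-gene pathogenicity from panel evidence.

Classification consumes three evidence streams per sample: small-variant
calls (with an effect class and a clinical pathogenicity class), gene-level
copy-number calls (log2 ratio with cutoff +/-1 for amplification/deletion),
and large-genome-rearrangement flags.  A gene is *deficient* (biallelically
inactivated) when it carries two distinct pathogenic alleles, one
pathogenic allele plus a deletion, a homozygous deletion, or a large
rearrangement.  Samples with exactly one pathogenic BRCA1/2 allele and no
second hit are *monoallelic pathogenic*; samples with no pathogenic
BRCA1/2 alteration at all are *intact*.  Monoallelic and intact together
form the BRCA *non-deficient* group.

Panel data carry no phase, so two distinct pathogenic variants in one gene
are assumed to be in trans (biallelic); the assumption is recorded in the
evidence list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BRCA_GENES",
    "BRCAStatus",
    "GeneCopyNumberCall",
    "RearrangementCall",
    "VariantCall",
    "classify_brca_status",
    "gene_cna_call",
    "hrr_deficiency",
    "is_pathogenic",
    "load_default_hrr_genes",
]

BRCA_GENES = frozenset({"BRCA1", "BRCA2"})

EFFECTS = frozenset(
    {"nonsense", "frameshift", "missense", "splice", "inframe_indel", "synonymous", "other"}
)
CLINICAL_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "unknown"}
)
TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift"})
PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})
RULE_SETS = frozenset({"acmg_brca", "clinvar_hrr"})


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    gene: str
    effect: str
    clinical_class: str
    origin: str  # somatic | germline
    allele_id: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.clinical_class not in CLINICAL_CLASSES:
            raise ValueError(f"unknown clinical class {self.clinical_class!r}")
        if self.origin not in ("somatic", "germline"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class GeneCopyNumberCall:
    sample_id: str
    gene: str
    log2_ratio: float
    call: str  # amplification | deletion | homozygous_deletion | neutral


@dataclass(frozen=True)
class RearrangementCall:
    sample_id: str
    gene: str
    description: str = "large genome rearrangement"


@dataclass(frozen=True)
class BRCAStatus:
    sample_id: str
    status: str  # deficient | intact | monoallelic_pathogenic
    evidence: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_deficient(self) -> bool:
        return self.status == "deficient"


def is_pathogenic(variant: VariantCall, rule_set: str = "acmg_brca") -> bool:
    """Truncating (nonsense/frameshift) or clinically pathogenic / likely
    pathogenic variants count as pathogenic; everything else does not.

    ``acmg_brca`` reads the clinical class as an ACMG assertion (BRCA1/2),
    ``clinvar_hrr`` as a ClinVar assertion (other HRR genes); the decision
    rule is identical, the rule set names the provenance expected of the
    annotation.
    """
    if rule_set not in RULE_SETS:
        raise ValueError(f"unknown rule set {rule_set!r}; expected one of {sorted(RULE_SETS)}")
    return variant.effect in TRUNCATING_EFFECTS or variant.clinical_class in PATHOGENIC_CLASSES


def gene_cna_call(log2_ratio: float, homdel_threshold: float = -2.0) -> str:
    """Discretize a gene-level log2 copy ratio.

    +1/-1 are the amplification/deletion cutoffs; ratios at or below
    ``homdel_threshold`` (default -2) are homozygous deletions.
    """
    if not math.isfinite(log2_ratio):
        raise ValueError(f"log2 ratio must be finite, got {log2_ratio!r}")
    if log2_ratio <= homdel_threshold:
        return "homozygous_deletion"
    if log2_ratio <= -1.0:
        return "deletion"
    if log2_ratio >= 1.0:
        return "amplification"
    return "neutral"


def _gene_deficiency(
    variants: Sequence[VariantCall],
    cnas: Sequence[GeneCopyNumberCall],
    rearrangements: Sequence[RearrangementCall],
    gene: str,
    rule_set: str,
) -> tuple[str, list[str]]:
    """Classify one gene as deficient / monoallelic_pathogenic / intact."""
    pathogenic = {v.allele_id: v for v in variants if v.gene == gene and is_pathogenic(v, rule_set)}
    n_alleles = len(pathogenic)  # distinct allele_ids: a germline variant re-seen somatically counts once
    evidence: list[str] = [
        f"{v.origin} {v.gene} {v.effect}/{v.clinical_class} allele={aid}"
        for aid, v in sorted(pathogenic.items())
    ]
    gene_cnas = [c for c in cnas if c.gene == gene]
    homdel = any(c.call == "homozygous_deletion" for c in gene_cnas)
    het_del = any(c.call == "deletion" for c in gene_cnas)
    rearranged = any(r.gene == gene for r in rearrangements)

    if homdel:
        evidence.append(f"{gene} homozygous deletion")
        return "deficient", evidence
    if rearranged:
        evidence.append(f"{gene} large genome rearrangement")
        return "deficient", evidence
    if n_alleles >= 2:
        evidence.append(f"{gene}: {n_alleles} distinct pathogenic alleles assumed in trans (no phase)")
        return "deficient", evidence
    if n_alleles == 1 and het_del:
        evidence.append(f"{gene} heterozygous deletion (second hit)")
        return "deficient", evidence
    if n_alleles == 1:
        return "monoallelic_pathogenic", evidence
    return "intact", []


def classify_brca_status(
    variants: Sequence[VariantCall],
    cnas: Sequence[GeneCopyNumberCall] = (),
    rearrangements: Sequence[RearrangementCall] = (),
    sample_id: str | None = None,
) -> BRCAStatus:
    """Three-way BRCA1/2 classification from pre-filtered BRCA evidence.

    Evidence must concern BRCA1/BRCA2 only (callers pre-filter); the sample
    is deficient if either gene is biallelically inactivated, monoallelic
    pathogenic if some gene carries exactly one pathogenic allele without a
    second hit, intact otherwise.
    """
    items = list(variants) + list(cnas) + list(rearrangements)
    foreign = sorted({e.gene for e in items if e.gene not in BRCA_GENES})
    if foreign:
        raise ValueError(f"evidence from non-BRCA gene(s) {foreign}; pre-filter to BRCA1/2")
    if sample_id is None:
        if not items:
            raise ValueError("sample_id required when no evidence is supplied")
        sample_id = items[0].sample_id

    per_gene = {
        g: _gene_deficiency(variants, cnas, rearrangements, g, "acmg_brca")
        for g in sorted(BRCA_GENES)
    }
    evidence = [e for _, ev in per_gene.values() for e in ev]
    if any(status == "deficient" for status, _ in per_gene.values()):
        return BRCAStatus(sample_id, "deficient", tuple(evidence))
    if any(status == "monoallelic_pathogenic" for status, _ in per_gene.values()):
        return BRCAStatus(sample_id, "monoallelic_pathogenic", tuple(evidence))
    return BRCAStatus(sample_id, "intact", tuple(evidence))


def hrr_deficiency(
    variants: Sequence[VariantCall],
    cnas: Sequence[GeneCopyNumberCall] = (),
    sample_id: str | None = None,
    hrr_genes: Iterable[str] | None = None,
) -> tuple[bool, dict[str, str]]:
    """Biallelic inactivation of any non-BRCA HRR-pathway gene.

    Applies the same deficient logic as :func:`classify_brca_status` to each
    gene of the HRR panel (BRCA1/2 excluded — they are handled by the BRCA
    classifier), under ClinVar pathogenicity.  Returns the overall flag and
    the per-gene status for every gene with any pathogenic evidence.
    """
    genes = list(load_default_hrr_genes() if hrr_genes is None else hrr_genes)
    if not genes:
        raise ValueError("HRR gene list must be non-empty")
    detail: dict[str, str] = {}
    for gene in genes:
        if gene in BRCA_GENES:
            continue
        status, _ = _gene_deficiency(variants, cnas, (), gene, "clinvar_hrr")
        if status != "intact":
            detail[gene] = status
    return any(s == "deficient" for s in detail.values()), detail


def load_default_hrr_genes(path: str | Path | None = None) -> list[str]:
    """The shipped provisional 25-gene HRR panel, or a user file (one symbol per line)."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("hrdscar.data").joinpath("hrr_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
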