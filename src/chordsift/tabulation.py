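"""Cohort-level summaries of retained variants.

Aggregates the per-record classification output into the counts a cohort
report needs: retained variants split into loss-of-function-like and
missense classes, distinct carriers, distinct genes, and distinct genes per
functional category. Also provides the cross-cohort replication restriction
(the replication cohort is screened only in genes that carried retained
variants in the discovery cohort) and the case-only tabulation against a
control genotype matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .model import (
    PATHWAY_LABEL_TO_CATEGORY,
    CohortGenotypes,
    GenePanel,
    VariantRecord,
)
from .pathogenicity import HIGH_IMPACT_TYPES, ClassificationResult
from .model import VariantType

__all__ = [
    "CohortSummary",
    "summarize",
    "carrier_count",
    "replication_gene_set",
    "case_only_variants",
]

VariantKey = tuple[str, int, str, str, str]


@dataclass(frozen=True)
class CohortSummary:
    n_variants_retained: int
    n_lof: int
    n_missense: int
    n_patients_with_variant: int
    fraction_patients: Fraction
    genes_retained: frozenset[str]
    genes_per_category: Mapping[str, int]
    multi_category_genes: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "n_variants_retained": self.n_variants_retained,
            "n_lof": self.n_lof,
            "n_missense": self.n_missense,
            "n_patients_with_variant": self.n_patients_with_variant,
            "fraction_patients": float(self.fraction_patients),
            "genes_retained": sorted(self.genes_retained),
            "genes_per_category": dict(sorted(self.genes_per_category.items())),
            "multi_category_genes": sorted(self.multi_category_genes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def summarize(
    retained: Sequence[tuple[VariantRecord, ClassificationResult]],
    panel: GenePanel,
    cohort_size: int,
) -> CohortSummary:
    """Summarize retained (record, classification) pairs for one cohort.

    Category attribution uses each row's printed pathway label when present;
    rows without a label contribute to every category of their gene in the
    panel, and genes with more than one panel category are flagged in
    ``multi_category_genes``. Distinct genes are counted per category;
    distinct carrier identifiers across all retained rows give the patient
    count (a compound printed identifier is one carrier).
    """
    if cohort_size <= 0:
        raise InputError("cohort_size must be positive")

    genes: set[str] = set()
    patients: set[str] = set()
    genes_by_category: dict[str, set[str]] = {}
    multi: set[str] = set()
    n_lof = n_missense = 0

    for rec, res in retained:
        if not res.retained:
            continue
        if rec.gene not in panel:
            raise InputError(f"gene {rec.gene} is not in the panel")
        genes.add(rec.gene)
        patients.update(rec.carriers)
        if rec.variant_type in HIGH_IMPACT_TYPES:
            n_lof += 1
        elif rec.variant_type is VariantType.MISSENSE:
            n_missense += 1
        if rec.pathway_label is not None:
            label = PATHWAY_LABEL_TO_CATEGORY.get(rec.pathway_label, rec.pathway_label)
            cats = [label]
        else:
            cats = sorted(panel.categories[rec.gene])
            if len(cats) > 1:
                multi.add(rec.gene)
        for cat in cats:
            genes_by_category.setdefault(cat, set()).add(rec.gene)

    n_retained = n_lof + n_missense + sum(
        1
        for rec, res in retained
        if res.retained
        and rec.variant_type not in HIGH_IMPACT_TYPES
        and rec.variant_type is not VariantType.MISSENSE
    )
    return CohortSummary(
        n_variants_retained=n_retained,
        n_lof=n_lof,
        n_missense=n_missense,
        n_patients_with_variant=len(patients),
        fraction_patients=Fraction(len(patients), cohort_size),
        genes_retained=frozenset(genes),
        genes_per_category={c: len(g) for c, g in genes_by_category.items()},
        multi_category_genes=frozenset(multi),
    )


def carrier_count(variant_key: VariantKey, records: Iterable[VariantRecord]) -> int:
    """Distinct carrier identifiers across all records matching the key."""
    carriers: set[str] = set()
    for rec in records:
        if rec.key == tuple(variant_key):
            carriers.update(rec.carriers)
    return len(carriers)


def replication_gene_set(discovery_summary: CohortSummary) -> frozenset[str]:
    """Genes carrying retained variants in the discovery cohort.

    The replication cohort is filtered within this gene set only.
    """
    if not discovery_summary.genes_retained:
        warnings.warn("discovery summary contains no retained genes; replication set is empty")
        return frozenset()
    return discovery_summary.genes_retained


def case_only_variants(
    retained_case_variants: Sequence[VariantRecord],
    control_genotypes: CohortGenotypes,
) -> frozenset[VariantKey]:
    """Variant keys carried by cases only, absent from every control.

    A key absent from the control matrix counts as a zero-carrier column
    (the variant was never called in controls).
    """
    if control_genotypes.phenotype is None or len(control_genotypes.phenotype) == 0:
        raise InputError("control genotypes must carry phenotype labels")
    controls = ~control_genotypes.phenotype
    control_count: dict[VariantKey, int] = {}
    for j, rec in enumerate(control_genotypes.variant_index):
        col = control_genotypes.dosage[controls, j]
        control_count[rec.key] = int((col > 0).sum())
    return frozenset(
        rec.key
        for rec in retained_case_variants
        if control_count.get(rec.key, 0) == 0
    )
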