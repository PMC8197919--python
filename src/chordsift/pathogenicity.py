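"""Composite pathogenicity classification.

A filtered variant is retained for study when at least one of four evidence
branches fires:

* ``HIGH_IMPACT`` — the consequence class itself is loss-of-function-like
  (frameshift, stop gain/loss, canonical splice site, or a
  structural-interaction call);
* ``INSILICO_TRIPLE`` — a missense variant called deleterious by both
  ensemble predictors (MetaSVM D and MetaLR D) with phred-scaled CADD ≥ 20;
* ``CLINVAR_PLP`` — asserted pathogenic or likely pathogenic in ClinVar;
* ``HGMD_DM`` — a disease-causing mutation class in HGMD.

The in-silico triple applies only to missense variants; high-impact classes
need no score support, and clinically asserted variants are retained even
when the in-silico scores are unremarkable (the rescue path: a benign-scored
missense change with a pathogenic ClinVar assertion stays in).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .model import AnnotationBundle, VariantRecord, VariantType

__all__ = [
    "Criterion",
    "ClassificationResult",
    "HIGH_IMPACT_TYPES",
    "is_high_impact",
    "insilico_triple",
    "classify",
    "classification_report",
]


class Criterion(str, Enum):
    HIGH_IMPACT = "HIGH_IMPACT"
    INSILICO_TRIPLE = "INSILICO_TRIPLE"
    CLINVAR_PLP = "CLINVAR_PLP"
    HGMD_DM = "HGMD_DM"


HIGH_IMPACT_TYPES = frozenset(
    {
        VariantType.FRAMESHIFT,
        VariantType.STOP_GAINED,
        VariantType.STOP_LOST,
        VariantType.SPLICE_SITE,
        VariantType.STRUCTURAL_INTERACTION,
    }
)

CADD_THRESHOLD = 20.0


@dataclass(frozen=True)
class ClassificationResult:
    retained: bool
    criteria: frozenset[Criterion]

    def __post_init__(self):
        if self.retained != bool(self.criteria):
            raise ValueError("retained must hold exactly when some criterion fired")

    @staticmethod
    def from_criteria(criteria: Iterable[Criterion]) -> "ClassificationResult":
        crit = frozenset(criteria)
        return ClassificationResult(retained=bool(crit), criteria=crit)


def is_high_impact(variant_type: VariantType) -> bool:
    """True for loss-of-function-like consequence classes.

    Non-canonical splice-region changes alone do not qualify; compound
    missense-and-splice-region rows carry primary type missense and go
    through the in-silico branch instead.
    """
    return variant_type in HIGH_IMPACT_TYPES


def insilico_triple(a: AnnotationBundle) -> bool:
    """MetaSVM D, MetaLR D and CADD ≥ 20, all three present.

    Any missing component fails the branch; the threshold is inclusive.
    """
    return (
        a.metasvm == "D"
        and a.metalr == "D"
        and a.cadd_phred is not None
        and a.cadd_phred >= CADD_THRESHOLD
    )


def classify(v: VariantRecord, a: AnnotationBundle) -> ClassificationResult:
    """Evaluate all four branches; retained iff at least one fires."""
    criteria = set()
    if is_high_impact(v.variant_type):
        criteria.add(Criterion.HIGH_IMPACT)
    if v.variant_type is VariantType.MISSENSE and insilico_triple(a):
        criteria.add(Criterion.INSILICO_TRIPLE)
    if a.clinvar in {"P", "LP"}:
        criteria.add(Criterion.CLINVAR_PLP)
    if a.hgmd == "DM":
        criteria.add(Criterion.HGMD_DM)
    return ClassificationResult.from_criteria(criteria)


def classification_report(
    records: list[VariantRecord], annotations: list[AnnotationBundle]
) -> pd.DataFrame:
    """Tabular report: one row per record with retained flag and criteria codes."""
    rows = []
    for rec, ann in zip(records, annotations):
        res = classify(rec, ann)
        rows.append(
            {
                "gene": rec.gene,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "variant_type": rec.variant_type.value,
                "protein_change": rec.protein_change,
                "carriers": ";".join(sorted(rec.carriers)),
                "retained": res.retained,
                "criteria": "|".join(sorted(c.value for c in res.criteria)),
            }
        )
    columns = [
        "gene", "chrom", "pos", "ref", "alt", "variant_type",
        "protein_change", "carriers", "retained", "criteria",
    ]
    return pd.DataFrame(rows, columns=columns)
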