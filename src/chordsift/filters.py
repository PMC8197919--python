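"""Sequential variant-level filter cascade.

Variants pass through three stages before pathogenicity classification:

1. call quality — pipeline flag, read depth, heterozygous allele balance
   (ABHet), and concordance across the configured variant callers;
2. consequence class — only potentially protein-altering classes are kept;
3. population frequency and internal-database specificity — a variant is
   too common if its minor allele frequency exceeds the threshold in an
   in-scope population database, or recurrent if seen in more than the
   allowed number of families in the internal reference database.

The frequency stage supports two combinators. ``any_criterion_excludes``
(the default) drops a variant when either the frequency or the recurrence
criterion fires; ``both_criteria_exclude`` drops it only when both fire.
Two population scopes are supported: ``ancestry_matched`` consults only
entries whose population tag is in the configured ancestry set (the
European-cohort dialect), ``any_population`` consults every entry (the
replication-cohort dialect, which also screens East-Asian frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable

from .errors import InputError
from .model import AnnotationBundle, VariantRecord, VariantType

__all__ = [
    "Reason",
    "QCFields",
    "FilterConfig",
    "FilterDecision",
    "apply_qc",
    "consequence_filter",
    "frequency_filter",
    "run_cascade",
    "DEFAULT_ALLOWED_CONSEQUENCES",
]


class Reason(str, Enum):
    LOW_DEPTH = "LOW_DEPTH"
    ABHET_OUT_OF_RANGE = "ABHET_OUT_OF_RANGE"
    SINGLE_CALLER = "SINGLE_CALLER"
    PIPELINE_FLAG = "PIPELINE_FLAG"
    SYNONYMOUS = "SYNONYMOUS"
    COMMON_IN_POPULATION = "COMMON_IN_POPULATION"
    RECURRENT_INHOUSE = "RECURRENT_INHOUSE"


@dataclass(frozen=True)
class QCFields:
    """Per-call quality fields. ``ab_het`` is None for homozygous calls."""

    read_depth: int
    ab_het: float | None = None
    caller_count: int = 3
    pipeline_flagged: bool = False


#: Consequence classes studied further: the protein-altering set plus
#: stop-lost extensions and structural-interaction calls.
DEFAULT_ALLOWED_CONSEQUENCES = frozenset(
    {
        VariantType.FRAMESHIFT,
        VariantType.STOP_GAINED,
        VariantType.STOP_LOST,
        VariantType.SPLICE_SITE,
        VariantType.INFRAME_INDEL,
        VariantType.MISSENSE,
        VariantType.STRUCTURAL_INTERACTION,
    }
)

#: Population tags consulted under the ancestry-matched (European) scope.
DEFAULT_ANCESTRY_POPULATIONS = frozenset({"NFE", "EUR", "EA"})


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    abhet_bounds: tuple[float, float] = (0.2, 0.8)
    min_callers: int = 2
    maf_threshold: float = 0.001
    frequency_population_scope: str = "ancestry_matched"  # or "any_population"
    ancestry_populations: frozenset[str] = DEFAULT_ANCESTRY_POPULATIONS
    max_inhouse_families: int = 2
    frequency_combinator: str = "any_criterion_excludes"  # or "both_criteria_exclude"
    allowed_consequences: frozenset[VariantType] = DEFAULT_ALLOWED_CONSEQUENCES

    def __post_init__(self):
        if self.min_depth < 0 or self.min_callers < 0 or self.max_inhouse_families < 0:
            raise InputError("filter thresholds must be non-negative")
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise InputError("maf_threshold must lie in [0, 1]")
        if self.frequency_population_scope not in {"ancestry_matched", "any_population"}:
            raise InputError(f"unknown population scope {self.frequency_population_scope!r}")
        if self.frequency_combinator not in {"any_criterion_excludes", "both_criteria_exclude"}:
            raise InputError(f"unknown frequency combinator {self.frequency_combinator!r}")

    def to_dict(self) -> dict:
        """Plain-mapping form for the package config document."""
        return {
            "min_depth": self.min_depth,
            "abhet_bounds": list(self.abhet_bounds),
            "min_callers": self.min_callers,
            "maf_threshold": self.maf_threshold,
            "frequency_population_scope": self.frequency_population_scope,
            "ancestry_populations": sorted(self.ancestry_populations),
            "max_inhouse_families": self.max_inhouse_families,
            "frequency_combinator": self.frequency_combinator,
            "allowed_consequences": sorted(v.value for v in self.allowed_consequences),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FilterConfig":
        doc = dict(doc)
        if "abhet_bounds" in doc:
            doc["abhet_bounds"] = tuple(doc["abhet_bounds"])
        if "ancestry_populations" in doc:
            doc["ancestry_populations"] = frozenset(doc["ancestry_populations"])
        if "allowed_consequences" in doc:
            doc["allowed_consequences"] = frozenset(
                VariantType(v) for v in doc["allowed_consequences"]
            )
        unknown = set(doc) - {f.name for f in fields(cls)}
        if unknown:
            raise InputError(f"unknown filter config key(s) {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class FilterDecision:
    retained: bool
    reasons: tuple[Reason, ...] = ()

    def __post_init__(self):
        if self.retained != (len(self.reasons) == 0):
            raise InputError("retained must hold exactly when no exclusion reason fired")

    @staticmethod
    def from_reasons(reasons: Iterable[Reason]) -> "FilterDecision":
        reasons = tuple(reasons)
        return FilterDecision(retained=not reasons, reasons=reasons)


def apply_qc(qc: QCFields, cfg: FilterConfig = FilterConfig()) -> FilterDecision:
    """Call-quality stage.

    Excludes on low depth, out-of-range heterozygous allele balance (skipped
    when ``ab_het`` is missing, i.e. homozygous calls), insufficient caller
    concordance, or the upstream pipeline flag.
    """
    if qc.read_depth < 0:
        raise InputError(f"read depth must be non-negative, got {qc.read_depth}")
    reasons = []
    if qc.read_depth < cfg.min_depth:
        reasons.append(Reason.LOW_DEPTH)
    if qc.ab_het is not None:
        lo, hi = cfg.abhet_bounds
        if qc.ab_het < lo or qc.ab_het > hi:
            reasons.append(Reason.ABHET_OUT_OF_RANGE)
    if qc.caller_count < cfg.min_callers:
        reasons.append(Reason.SINGLE_CALLER)
    if qc.pipeline_flagged:
        reasons.append(Reason.PIPELINE_FLAG)
    return FilterDecision.from_reasons(reasons)


def consequence_filter(v: VariantRecord, cfg: FilterConfig = FilterConfig()) -> FilterDecision:
    """Consequence stage: retain only allowed (protein-altering) classes.

    The single reason code covers every non-qualifying class, synonymous
    changes being the archetype.
    """
    if v.variant_type in cfg.allowed_consequences:
        return FilterDecision(retained=True)
    return FilterDecision.from_reasons([Reason.SYNONYMOUS])


def _in_scope_mafs(a: AnnotationBundle, cfg: FilterConfig) -> list[float]:
    if cfg.frequency_population_scope == "any_population":
        return list(a.maf_by_source.values())
    return [f for (db, pop), f in a.maf_by_source.items() if pop in cfg.ancestry_populations]


def frequency_filter(a: AnnotationBundle, cfg: FilterConfig = FilterConfig()) -> FilterDecision:
    """Frequency/specificity stage.

    Criterion A: the maximum in-scope database frequency exceeds the rarity
    threshold (missing entries contribute nothing — absence from a database
    is evidence of rarity, not a zero observation). Criterion B: recurrence
    in more than the allowed number of internal-database families. The
    configured combinator decides whether either (default) or both criteria
    must fire to exclude.
    """
    mafs = _in_scope_mafs(a, cfg)
    too_common = bool(mafs) and max(mafs) > cfg.maf_threshold
    recurrent = a.inhouse_family_count > cfg.max_inhouse_families

    if cfg.frequency_combinator == "any_criterion_excludes":
        fired = (too_common, recurrent)
    else:  # both_criteria_exclude: the literal conjunctive reading
        fired = (too_common and recurrent,) * 2 if (too_common and recurrent) else (False, False)
    reasons = [
        code
        for code, hit in zip((Reason.COMMON_IN_POPULATION, Reason.RECURRENT_INHOUSE), fired)
        if hit
    ]
    return FilterDecision.from_reasons(reasons)


def run_cascade(
    v: VariantRecord,
    qc: QCFields | None,
    a: AnnotationBundle,
    cfg: FilterConfig = FilterConfig(),
    skip_stages: frozenset[str] = frozenset(),
) -> FilterDecision:
    """Compose QC → consequence → frequency for one variant.

    ``skip_stages`` (subset of {"qc", "frequency"}) marks stages whose
    outcome the input already reflects, e.g. tables that print only
    post-filter variants. Reasons from the executed stages accumulate in
    stage order; the variant is retained iff every stage retains it.
    """
    reasons: list[Reason] = []
    if "qc" not in skip_stages:
        if qc is None:
            raise InputError("QC fields required unless the qc stage is pre-passed")
        reasons.extend(apply_qc(qc, cfg).reasons)
    reasons.extend(consequence_filter(v, cfg).reasons)
    if "frequency" not in skip_stages:
        reasons.extend(frequency_filter(a, cfg).reasons)
    return FilterDecision.from_reasons(reasons)
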