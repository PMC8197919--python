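"""Synthetic annotated case-control cohorts with known ground truth.

The generator emulates the study design the analysis modules assume: a
candidate-gene panel screened in a case-control cohort (defaults: 138 cases
versus 598 controls), rare unlinked variants drawn per gene from a MAF
spectrum, Hardy–Weinberg genotype sampling with an optional carrier-scale
odds ratio applied to cases of enriched genes or categories, and annotation
and QC fields planted per variant so that every pipeline stage has a known
expected outcome.

Every source of randomness flows from a single required seed through named
sub-streams, so identical configurations reproduce bit-identical cohorts
and individual stages can be regenerated independently.

The generator emits only observed variants (at least one carrier in the
cohort), like a real call set; the returned :class:`SyntheticTruth` covers
every emitted variant and records, per variant, its true MAF, enrichment
unit and odds ratio, the planted pathogenicity branch, and any planted
filter-failure reasons, plus the realized case-only key set.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, InputError
from .filters import QCFields, Reason
from .model import (
    CATEGORY_LABELS,
    AnnotationBundle,
    CohortGenotypes,
    FixtureBundle,
    GenePanel,
    VariantRecord,
    VariantType,
    build_panel,
    default_panel,
)

__all__ = [
    "AnnotationModel",
    "QCModel",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationResult",
    "simulate_cohort",
    "scenario",
    "synthetic_panel",
]

BRANCHES = ("HIGH_IMPACT", "INSILICO_TRIPLE", "CLINVAR_PLP", "HGMD_DM", "NONE")

#: Deterministic annotation profile per planted branch: each profile makes
#: exactly its branch fire in the classifier (and NONE fires no branch).
_BRANCH_PROFILES = {
    "HIGH_IMPACT": dict(variant_type=VariantType.FRAMESHIFT, metasvm=None, metalr=None,
                        cadd=None, clinvar=None, hgmd=None),
    "INSILICO_TRIPLE": dict(variant_type=VariantType.MISSENSE, metasvm="D", metalr="D",
                            cadd=28.0, clinvar=None, hgmd=None),
    "CLINVAR_PLP": dict(variant_type=VariantType.MISSENSE, metasvm="T", metalr="T",
                        cadd=4.0, clinvar="P", hgmd=None),
    "HGMD_DM": dict(variant_type=VariantType.MISSENSE, metasvm="T", metalr="T",
                    cadd=4.0, clinvar=None, hgmd="DM"),
    "NONE": dict(variant_type=VariantType.MISSENSE, metasvm="D", metalr="T",
                 cadd=15.0, clinvar=None, hgmd=None),
}

_FAILURE_CYCLE = (
    None, None,
    Reason.LOW_DEPTH, Reason.ABHET_OUT_OF_RANGE, Reason.SINGLE_CALLER,
    Reason.PIPELINE_FLAG, Reason.SYNONYMOUS, Reason.COMMON_IN_POPULATION,
    Reason.RECURRENT_INHOUSE,
)


@dataclass(frozen=True)
class AnnotationModel:
    """Probabilities of the planted pathogenicity branch per variant.

    With ``deterministic=True`` (default) each branch maps to a fixed
    annotation profile that triggers exactly that branch, which makes the
    planted retained set exactly recoverable by the cascade + classifier.
    """

    branch_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "HIGH_IMPACT": 0.10,
            "INSILICO_TRIPLE": 0.30,
            "CLINVAR_PLP": 0.10,
            "HGMD_DM": 0.10,
            "NONE": 0.40,
        }
    )
    deterministic: bool = True

    def __post_init__(self):
        probs = dict(self.branch_probs)
        if set(probs) != set(BRANCHES):
            raise ConfigurationError(f"branch_probs must cover exactly {BRANCHES}")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"branch probabilities must sum to 1, got {total}")
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError("branch probabilities must be non-negative")
        if not self.deterministic:
            raise ConfigurationError(
                "only the deterministic-by-branch annotation model is implemented"
            )


@dataclass(frozen=True)
class QCModel:
    """Distributions of per-call QC fields for non-failing records."""

    depth_mean: float = 40.0
    abhet_range: tuple[float, float] = (0.35, 0.65)
    caller_count: int = 3
    failure_fractions: Mapping[str, float] = field(default_factory=dict)
    failure_plan: str = "random"  # or "cycle" (guarantees reason coverage)

    def __post_init__(self):
        for name, frac in self.failure_fractions.items():
            if name not in Reason.__members__:
                raise ConfigurationError(f"unknown failure reason {name!r}")
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("failure fractions must lie in [0, 1]")
        if self.failure_plan not in {"random", "cycle"}:
            raise ConfigurationError(f"unknown failure plan {self.failure_plan!r}")


@dataclass(frozen=True)
class SimulationConfig:
    panel: GenePanel
    seed: int
    n_cases: int = 138
    n_controls: int = 598
    maf_range: tuple[float, float] = (1e-5, 1e-3)  # log-uniform spectrum
    variants_per_gene: float = 3.0  # Poisson mean
    enrichment: Mapping[str, float] = field(default_factory=dict)  # gene/category -> carrier OR
    annotation_model: AnnotationModel = AnnotationModel()
    qc_model: QCModel = QCModel()
    case_only_genes: tuple[str, ...] = ()
    case_only_carrier_prob: float = 0.02

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.01):
            raise ConfigurationError("MAF spectrum must lie within (0, 0.01]")
        if self.variants_per_gene <= 0:
            raise ConfigurationError("variants_per_gene must be positive")
        for unit, odds in self.enrichment.items():
            if odds <= 0:
                raise ConfigurationError(f"odds ratio for {unit} must be positive")
        if not (0.0 <= self.case_only_carrier_prob <= 1.0):
            raise ConfigurationError("case_only_carrier_prob must lie in [0, 1]")
        unknown = set(self.case_only_genes) - set(self.panel.genes)
        if unknown:
            raise ConfigurationError(f"case-only genes not in panel: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    true_maf: dict[tuple, float] = field(default_factory=dict)
    unit: dict[tuple, str] = field(default_factory=dict)
    odds_ratio: dict[tuple, float] = field(default_factory=dict)
    branch: dict[tuple, str] = field(default_factory=dict)
    fail_reasons: dict[tuple, tuple[str, ...]] = field(default_factory=dict)
    case_only_planted: set = field(default_factory=set)
    case_only_keys: set = field(default_factory=set)

    @property
    def retained_keys(self) -> frozenset:
        """Keys the cascade + classifier should retain (deterministic model)."""
        return frozenset(
            k
            for k, br in self.branch.items()
            if br != "NONE" and not self.fail_reasons.get(k)
        )

    def to_json(self) -> str:
        def enc(key):
            return "|".join(str(x) for x in key)

        return json.dumps(
            {
                "true_maf": {enc(k): v for k, v in self.true_maf.items()},
                "unit": {enc(k): v for k, v in self.unit.items()},
                "odds_ratio": {enc(k): v for k, v in self.odds_ratio.items()},
                "branch": {enc(k): v for k, v in self.branch.items()},
                "fail_reasons": {enc(k): list(v) for k, v in self.fail_reasons.items()},
                "case_only_planted": sorted(enc(k) for k in self.case_only_planted),
                "case_only_keys": sorted(enc(k) for k in self.case_only_keys),
            },
            indent=1,
        )


@dataclass
class SimulationResult:
    cohort: CohortGenotypes
    annotations: list[AnnotationBundle]
    qc: list[QCFields]
    truth: SyntheticTruth
    config: SimulationConfig


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def synthetic_panel(n_genes: int) -> GenePanel:
    """A deterministic panel of ``n_genes`` synthetic genes spread round-robin
    over the seven functional categories."""
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    cats = sorted(CATEGORY_LABELS)
    doc: dict[str, list[str]] = {c: [] for c in cats}
    for i in range(n_genes):
        doc[cats[i % len(cats)]].append(f"GENE{i + 1:04d}")
    return build_panel({c: g for c, g in doc.items() if g})


def _odds_ratio_for(gene: str, panel: GenePanel, enrichment: Mapping[str, float]) -> tuple[float, str]:
    if gene in enrichment:
        return float(enrichment[gene]), gene
    best, unit = 1.0, gene
    for cat in sorted(panel.categories[gene]):
        if cat in enrichment and enrichment[cat] != 1.0:
            if abs(np.log(enrichment[cat])) > abs(np.log(best)):
                best, unit = float(enrichment[cat]), cat
    return best, unit


def simulate_cohort(cfg: SimulationConfig) -> SimulationResult:
    """Draw one annotated cohort; identical config (incl. seed) → identical output."""
    rng_struct = _stream(cfg.seed, "structure")
    rng_geno = _stream(cfg.seed, "genotypes")
    rng_qc = _stream(cfg.seed, "qc")
    rng_ann = _stream(cfg.seed, "annotations")

    n = cfg.n_cases + cfg.n_controls
    sample_ids = [f"case_{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    phenotype = np.zeros(n, dtype=bool)
    phenotype[: cfg.n_cases] = True

    genes = sorted(cfg.panel.genes)
    lo, hi = cfg.maf_range
    records: list[VariantRecord] = []
    annotations: list[AnnotationBundle] = []
    qc_fields: list[QCFields] = []
    columns: list[np.ndarray] = []
    truth = SyntheticTruth()
    fail_cursor = 0
    branch_names = list(BRANCHES)
    branch_p = [cfg.annotation_model.branch_probs[b] for b in branch_names]
    fail_items = sorted(cfg.qc_model.failure_fractions.items())

    for gi, gene in enumerate(genes):
        m_g = rng_struct.poisson(cfg.variants_per_gene)
        if m_g == 0:
            continue
        odds, unit = _odds_ratio_for(gene, cfg.panel, cfg.enrichment)
        case_only = gene in cfg.case_only_genes
        chrom = str(gi % 22 + 1)
        for k in range(m_g):
            maf = float(np.exp(rng_struct.uniform(np.log(lo), np.log(hi))))
            q0 = 1.0 - (1.0 - maf) ** 2  # control carrier probability (HWE)
            if case_only:
                q_ctrl, q_case = 0.0, cfg.case_only_carrier_prob
            else:
                odds1 = odds * q0 / (1.0 - q0)
                q_ctrl, q_case = q0, odds1 / (1.0 + odds1)

            carrier = np.where(
                phenotype,
                rng_geno.random(n) < q_case,
                rng_geno.random(n) < q_ctrl,
            )
            # homozygous alternates among carriers follow conditional HWE
            p_hom = maf**2 / q0
            dosage = np.where(carrier, np.where(rng_geno.random(n) < p_hom, 2, 1), 0)
            if not dosage.any():
                continue  # unobserved in this cohort; not emitted

            branch = branch_names[rng_ann.choice(len(branch_names), p=branch_p)]
            if cfg.qc_model.failure_plan == "cycle":
                planted = _FAILURE_CYCLE[fail_cursor % len(_FAILURE_CYCLE)]
                fail_cursor += 1
            else:
                planted = None
                u = rng_qc.random()
                acc = 0.0
                for name, frac in fail_items:
                    acc += frac
                    if u < acc:
                        planted = Reason[name]
                        break

            profile = _BRANCH_PROFILES[branch]
            vtype = profile["variant_type"]
            if planted is Reason.SYNONYMOUS:
                vtype = VariantType.SYNONYMOUS

            pos = (gi + 1) * 1_000_000 + k * 100 + 1
            rec = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="A",
                alt="G",
                gene=gene,
                variant_type=vtype,
                protein_change="",
                carriers=frozenset(s for s, d in zip(sample_ids, dosage) if d > 0),
                printed_type=vtype.value,
                impact="high" if vtype is VariantType.FRAMESHIFT else "moderate",
            )
            maf_sources: dict[tuple[str, str], float] = {}
            inhouse = 0
            if planted is Reason.COMMON_IN_POPULATION:
                maf_sources[("gnomad_exomes", "NFE")] = 0.05
            if planted is Reason.RECURRENT_INHOUSE:
                inhouse = 5
            ann = AnnotationBundle(
                maf_by_source=maf_sources,
                inhouse_family_count=inhouse,
                metasvm=profile["metasvm"],
                metalr=profile["metalr"],
                cadd_phred=profile["cadd"],
                clinvar=profile["clinvar"],
                hgmd=profile["hgmd"],
            )

            depth = int(10 + rng_qc.poisson(max(cfg.qc_model.depth_mean - 10, 1)))
            abhet = float(rng_qc.uniform(*cfg.qc_model.abhet_range))
            callers = cfg.qc_model.caller_count
            flagged = False
            if planted is Reason.LOW_DEPTH:
                depth = 5
            elif planted is Reason.ABHET_OUT_OF_RANGE:
                abhet = 0.05
            elif planted is Reason.SINGLE_CALLER:
                callers = 1
            elif planted is Reason.PIPELINE_FLAG:
                flagged = True
            qc = QCFields(read_depth=depth, ab_het=abhet, caller_count=callers,
                          pipeline_flagged=flagged)

            key = rec.key
            truth.true_maf[key] = maf
            truth.unit[key] = unit
            truth.odds_ratio[key] = odds if not case_only else float("inf")
            truth.branch[key] = branch
            truth.fail_reasons[key] = (planted.value,) if planted else ()
            if case_only:
                truth.case_only_planted.add(key)
            if not dosage[~phenotype].any():
                truth.case_only_keys.add(key)

            records.append(rec)
            annotations.append(ann)
            qc_fields.append(qc)
            columns.append(dosage.astype(np.int8))

    if not records:
        raise ConfigurationError("configuration produced no observed variants")
    dosage_matrix = np.column_stack(columns)
    cohort = CohortGenotypes(
        sample_ids=sample_ids,
        phenotype=phenotype,
        dosage=dosage_matrix,
        variant_index=records,
    )
    return SimulationResult(cohort, annotations, qc_fields, truth, cfg)


def to_table_bundle(sim: SimulationResult) -> FixtureBundle:
    """View a simulated cohort in the fixtures' tabular dialect.

    One row per variant with its annotation evidence; the row's ID column
    carries one representative carrier (the dialect is one-carrier-per-row).
    """
    import pandas as pd

    ids = sorted({min(rec.carriers) for rec in sim.cohort.variant_index})
    patients = pd.DataFrame(
        {"ID": ids, "Gender": "NA", "Age": "NA", "Morphology": "NA", "Site": "NA"}
    )
    return FixtureBundle(
        name="synthetic",
        dialect="european",
        records=list(sim.cohort.variant_index),
        annotations=list(sim.annotations),
        patients=patients,
        prepassed_stages=frozenset(),
    )


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Fully specified configurations mirroring the study's analyses.

    * ``null`` — 500 genes, no enrichment anywhere; used for burden-test
      type-I-error calibration.
    * ``filter_stress`` — cycles a planted filter-failure reason through the
      variants so every exclusion reason code is exercised.
    * ``enriched_notochord`` — carrier odds ratio 5 on the notochord category
      of the bundled panel, everything else null.
    * ``case_only`` — three genes whose variants occur exclusively in cases.

    Calibration-oriented scenarios draw MAFs log-uniformly from [1e-3, 1e-2]
    (the upper part of the admissible spectrum) so that variants are actually
    polymorphic at the default cohort size; the discovery-pipeline default of
    [1e-5, 1e-3] leaves most sites monomorphic in 736 samples, where no score
    test is informative.
    """
    calib_maf = (1e-3, 1e-2)
    if name == "null":
        return SimulationConfig(panel=synthetic_panel(500), seed=seed, maf_range=calib_maf)
    if name == "filter_stress":
        return SimulationConfig(
            panel=synthetic_panel(14),
            seed=seed,
            maf_range=calib_maf,
            qc_model=QCModel(failure_plan="cycle"),
        )
    if name == "enriched_notochord":
        return SimulationConfig(
            panel=default_panel(),
            seed=seed,
            maf_range=calib_maf,
            enrichment={"notochord": 5.0},
        )
    if name == "case_only":
        panel = synthetic_panel(20)
        genes = sorted(panel.genes)[:3]
        return SimulationConfig(
            panel=panel, seed=seed, maf_range=calib_maf, case_only_genes=tuple(genes)
        )
    raise InputError(f"unknown scenario {name!r}")
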