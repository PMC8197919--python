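"""Core data model: variants, annotations, gene panels, cohorts, fixtures.

The package analyses candidate-gene rare germline variants in case-control
chordoma cohorts. Two transcribed variant tables ship with the package: the
European-ancestry discovery cohort (34 variant-carrier records) and the
Chinese skull-base replication cohort (20 records). Each table row is one
observed variant in one (or, after aggregation, several) carrier(s), together
with its external annotation evidence: ensemble in-silico calls (MetaSVM /
MetaLR), phred-scaled CADD, ClinVar / HGMD clinical classes, and population
allele frequencies from gnomAD exomes / genomes in the ancestry-matched
population (NFE or EAS).

Coordinates are 1-based on GRCh37/hg19, matching the printed tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, FixtureError, InputError

__all__ = [
    "VariantType",
    "VariantRecord",
    "AnnotationBundle",
    "GenePanel",
    "CohortGenotypes",
    "FixtureBundle",
    "load_fixture",
    "build_panel",
    "load_panel",
    "default_panel",
    "write_table",
    "read_table",
    "CATEGORY_LABELS",
    "PATHWAY_LABEL_TO_CATEGORY",
]


class VariantType(str, Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    SPLICE_SITE = "splice_site"
    SPLICE_REGION = "splice_region"
    INFRAME_INDEL = "inframe_indel"
    STRUCTURAL_INTERACTION = "structural_interaction"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Severity order used to pick the primary type of compound printed types
#: such as "frameshift & stop_gained" (each row is counted once, under its
#: most severe consequence).
SEVERITY_ORDER = (
    VariantType.FRAMESHIFT,
    VariantType.STOP_GAINED,
    VariantType.STOP_LOST,
    VariantType.SPLICE_SITE,
    VariantType.STRUCTURAL_INTERACTION,
    VariantType.INFRAME_INDEL,
    VariantType.MISSENSE,
    VariantType.SPLICE_REGION,
    VariantType.SYNONYMOUS,
    VariantType.OTHER,
)

_TYPE_ALIASES = {
    "missense": VariantType.MISSENSE,
    "frameshift": VariantType.FRAMESHIFT,
    "stop_gained": VariantType.STOP_GAINED,
    "stop gained": VariantType.STOP_GAINED,
    "stop/gain": VariantType.STOP_GAINED,
    "stop_lost": VariantType.STOP_LOST,
    "stop lost": VariantType.STOP_LOST,
    "splice_site": VariantType.SPLICE_SITE,
    "splice site": VariantType.SPLICE_SITE,
    "splice_region": VariantType.SPLICE_REGION,
    "splice region": VariantType.SPLICE_REGION,
    "inframe_indel": VariantType.INFRAME_INDEL,
    "structural interaction": VariantType.STRUCTURAL_INTERACTION,
    "structural_interaction": VariantType.STRUCTURAL_INTERACTION,
    "synonymous": VariantType.SYNONYMOUS,
    "other": VariantType.OTHER,
}


def parse_variant_type(printed: str) -> VariantType:
    """Map a printed (possibly compound) consequence string to its primary type.

    Compound strings like ``"frameshift & stop_gained"`` or
    ``"missense & splice region"`` resolve to the most severe component under
    :data:`SEVERITY_ORDER`; the caller is expected to preserve the full
    printed string separately.
    """
    parts = [p.strip().lower() for p in printed.split("&")]
    members = []
    for p in parts:
        if p not in _TYPE_ALIASES:
            raise InputError(f"unknown variant type {p!r} in {printed!r}")
        members.append(_TYPE_ALIASES[p])
    return min(members, key=SEVERITY_ORDER.index)


@dataclass(frozen=True)
class VariantRecord:
    """One observed variant-carrier record.

    ``variant_type`` is the primary consequence; the verbatim printed string
    (which may be compound) is kept in ``printed_type``. ``pathway_label`` is
    the single functional-category attribution printed with the row, if any.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_type: VariantType
    protein_change: str = ""
    carriers: frozenset[str] = frozenset()
    rsid: str | None = None
    printed_type: str = ""
    impact: str = ""
    pathway_label: str | None = None
    observed: bool = True

    def __post_init__(self):
        if self.pos <= 0:
            raise InputError(f"position must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not isinstance(self.variant_type, VariantType):
            raise InputError(f"variant_type must be a VariantType, got {self.variant_type!r}")
        if self.observed and not self.carriers:
            raise InputError(f"observed variant {self.gene} {self.chrom}:{self.pos} has no carriers")

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        """(chrom, pos, ref, alt, gene) — the identity used for aggregation."""
        return (self.chrom, self.pos, self.ref, self.alt, self.gene)


@dataclass(frozen=True)
class AnnotationBundle:
    """External evidence attached to one variant.

    ``maf_by_source`` maps (database, population) to an allele frequency in
    [0, 1]; an absent key means the variant was not observed in that source,
    which is deliberately distinct from an explicit frequency of zero.
    ``metasvm``/``metalr`` are the ensemble predictors' categorical calls
    ("D" deleterious / "T" tolerated), ``cadd_phred`` the phred-scaled CADD
    score; ``clinvar`` in {"P", "LP", "other"} and ``hgmd`` in {"DM", "other"};
    ``None`` throughout means the annotation is missing.
    """

    maf_by_source: Mapping[tuple[str, str], float] = field(default_factory=dict)
    inhouse_family_count: int = 0
    metasvm: str | None = None
    metalr: str | None = None
    cadd_phred: float | None = None
    clinvar: str | None = None
    hgmd: str | None = None

    def __post_init__(self):
        for key, f in self.maf_by_source.items():
            if not (0.0 <= f <= 1.0):
                raise InputError(f"allele frequency {f} for {key} outside [0, 1]")
        if self.inhouse_family_count < 0:
            raise InputError("inhouse_family_count must be non-negative")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise InputError("cadd_phred must be non-negative when present")
        for name, val, allowed in (
            ("metasvm", self.metasvm, {"D", "T"}),
            ("metalr", self.metalr, {"D", "T"}),
            ("clinvar", self.clinvar, {"P", "LP", "other"}),
            ("hgmd", self.hgmd, {"DM", "other"}),
        ):
            if val is not None and val not in allowed:
                raise InputError(f"{name} must be one of {sorted(allowed)} or None, got {val!r}")


CATEGORY_LABELS = frozenset(
    {
        "super_enhancer_essential",
        "notochord",
        "mesoderm_commitment",
        "swi_snf",
        "pi3k_akt_mtor",
        "sonic_hedgehog",
        "driver",
    }
)

#: Printed Pathway/Process strings -> canonical category labels.
PATHWAY_LABEL_TO_CATEGORY = {
    "T super-enhancer": "super_enhancer_essential",
    "Notochord development": "notochord",
    "Mesoderm commitment": "mesoderm_commitment",
    "SWI/SNF complex": "swi_snf",
    "PI3K/AKT/mTOR": "pi3k_akt_mtor",
    "Sonic Hedgehog": "sonic_hedgehog",
    "Driver": "driver",
}
_CATEGORY_TO_PATHWAY_LABEL = {v: k for k, v in PATHWAY_LABEL_TO_CATEGORY.items()}


@dataclass(frozen=True)
class GenePanel:
    """Gene -> set of functional category labels (a gene may carry several)."""

    categories: Mapping[str, frozenset[str]]

    def __post_init__(self):
        if not self.categories:
            raise ConfigurationError("gene panel must contain at least one gene")
        for gene, cats in self.categories.items():
            if not cats:
                raise ConfigurationError(f"gene {gene} has an empty category set")
            unknown = set(cats) - CATEGORY_LABELS
            if unknown:
                raise ConfigurationError(f"unknown category label(s) {sorted(unknown)} for gene {gene}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.categories)

    def genes_in_category(self, category: str) -> frozenset[str]:
        if category not in CATEGORY_LABELS:
            raise ConfigurationError(f"unknown category label {category!r}")
        return frozenset(g for g, cats in self.categories.items() if category in cats)

    def __contains__(self, gene: str) -> bool:
        return gene in self.categories


def build_panel(config_source: Mapping[str, Iterable[str]]) -> GenePanel:
    """Build a :class:`GenePanel` from a category -> gene-list mapping.

    Genes listed under several categories receive the union of their labels.
    """
    if not config_source:
        raise ConfigurationError("empty panel document")
    categories: dict[str, set[str]] = {}
    for label, genes in config_source.items():
        if label not in CATEGORY_LABELS:
            raise ConfigurationError(f"unknown category label {label!r}")
        for gene in genes or []:
            categories.setdefault(str(gene), set()).add(label)
    if not categories:
        raise ConfigurationError("panel document lists no genes")
    return GenePanel({g: frozenset(c) for g, c in categories.items()})


def load_panel(path: str | Path) -> GenePanel:
    """Load a panel from a YAML document mapping category -> gene list."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read panel document {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"panel document {path} must be a mapping of category -> gene list")
    return build_panel(doc)


def default_panel() -> GenePanel:
    """The bundled panel covering the genes of the two packaged cohorts."""
    return load_panel(_data_path("panel.yaml"))


@dataclass
class CohortGenotypes:
    """Samples × variants dosage matrix with case/control labels.

    ``dosage`` entries are 0/1/2 alternate-allele counts, -1 for missing.
    """

    sample_ids: list[str]
    phenotype: "pd.Series | list[bool]"
    dosage: "object"  # numpy array, kept loosely typed to avoid import cycle
    variant_index: list[VariantRecord]

    def __post_init__(self):
        import numpy as np

        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or n != len(self.phenotype):
            raise InputError("dosage rows must match sample_ids and phenotype length")
        if m != len(self.variant_index):
            raise InputError("dosage columns must match variant_index length")
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise InputError("dosage entries must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def carriers_of(self, j: int) -> frozenset[str]:
        col = self.dosage[:, j]
        return frozenset(s for s, d in zip(self.sample_ids, col) if d > 0)

    def check_carrier_consistency(self) -> bool:
        """True iff every column's record carriers equal samples with dosage>0."""
        return all(self.carriers_of(j) == self.variant_index[j].carriers for j in range(self.n_variants))


# ---------------------------------------------------------------------------
# Fixture / table IO

_FIXTURES = {
    "european_table1": ("european_table1.tsv", "european", "NFE"),
    "chinese_table2": ("chinese_table2.tsv", "chinese", "EAS"),
}

_COMMON_COLUMNS = [
    "ID", "Gender", "Age", "Morphology", "Gene", "Chr", "Location", "SNP IDS",
    "REF", "VAR", "Variant Type", "Protein Change", "Variant Impact",
    "METASVM", "METALR", "CADD", "HGMD/ClinVar",
]


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("chordsift.data") / name)


@dataclass
class FixtureBundle:
    """A loaded variant table: records, annotations, patient metadata.

    ``prepassed_stages`` records which cascade stages the table already
    reflects: the printed tables contain post-QC, post-frequency variants, so
    both stages are marked pre-passed and downstream analysis starts at the
    pathogenicity classification.
    """

    name: str
    dialect: str
    records: list[VariantRecord]
    annotations: list[AnnotationBundle]
    patients: pd.DataFrame
    prepassed_stages: frozenset[str] = frozenset({"qc", "frequency"})

    def items(self):
        return list(zip(self.records, self.annotations))


def _parse_row(row: pd.Series, population: str) -> tuple[VariantRecord, AnnotationBundle]:
    def cell(col: str) -> str:
        val = row.get(col)
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return ""
        return str(val).strip()

    printed_type = cell("Variant Type")
    record = VariantRecord(
        chrom=cell("Chr"),
        pos=int(row["Location"]),
        ref=cell("REF"),
        alt=cell("VAR"),
        gene=cell("Gene"),
        variant_type=parse_variant_type(printed_type),
        protein_change=cell("Protein Change"),
        carriers=frozenset({cell("ID")}),
        rsid=cell("SNP IDS") or None,
        printed_type=printed_type,
        impact=cell("Variant Impact"),
        pathway_label=cell("Pathway/Process") or None,
    )

    clinvar = hgmd = None
    clinical = cell("HGMD/ClinVar")
    if clinical:
        for tok in clinical.split("/"):
            tok = tok.strip()
            if tok in {"P", "LP"}:
                clinvar = tok
            elif tok == "DM":
                hgmd = tok
            elif tok:
                # any other printed class maps to the non-triggering bucket
                if tok.upper() == tok and tok in {"B", "VUS"}:
                    clinvar = "other"
                else:
                    hgmd = "other"

    maf: dict[tuple[str, str], float] = {}
    for db, col in (("gnomad_exomes", f"gnomAD Exomes {population}"),
                    ("gnomad_genomes", f"gnomAD Genomes {population}")):
        val = cell(col)
        if val != "":
            maf[(db, population)] = float(val)

    ann = AnnotationBundle(
        maf_by_source=maf,
        inhouse_family_count=0,
        metasvm=cell("METASVM") or None,
        metalr=cell("METALR") or None,
        cadd_phred=float(cell("CADD")) if cell("CADD") else None,
        clinvar=clinvar,
        hgmd=hgmd,
    )
    return record, ann


def read_table(path: str | Path, dialect: str = "european") -> FixtureBundle:
    """Read a variant table in the bundled tab-separated dialect."""
    population = "NFE" if dialect == "european" else "EAS"
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise FixtureError(f"cannot load variant table {path}: {exc}") from exc
    missing = [c for c in _COMMON_COLUMNS if c not in df.columns]
    if missing:
        raise FixtureError(f"variant table {path} lacks required column(s) {missing}")

    records, annotations = [], []
    for _, row in df.iterrows():
        rec, ann = _parse_row(row, population)
        records.append(rec)
        annotations.append(ann)

    meta_cols = [c for c in ("ID", "Gender", "Age", "Morphology", "Site") if c in df.columns]
    patients = df[meta_cols].drop_duplicates(subset="ID").reset_index(drop=True)
    return FixtureBundle(
        name=str(path), dialect=dialect, records=records,
        annotations=annotations, patients=patients,
    )


def load_fixture(name: str) -> FixtureBundle:
    """Load one of the packaged cohort tables.

    ``european_table1`` is the 34-record European-ancestry discovery table;
    ``chinese_table2`` the 20-record Chinese replication table. Both load with
    QC and frequency stages marked pre-passed (the tables print only variants
    that survived those stages).
    """
    if name not in _FIXTURES:
        raise FixtureError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    fname, dialect, _ = _FIXTURES[name]
    path = _data_path(fname)
    if not path.exists():
        raise FixtureError(f"fixture file missing: {path}")
    bundle = read_table(path, dialect=dialect)
    bundle.name = name
    return bundle


def write_table(bundle: FixtureBundle, path: str | Path) -> None:
    """Write a bundle back to the tab-separated table dialect.

    Round-trips with :func:`read_table`: re-reading reproduces the records and
    annotations field-by-field.
    """
    population = "NFE" if bundle.dialect == "european" else "EAS"
    meta = bundle.patients.set_index("ID") if "ID" in bundle.patients.columns else pd.DataFrame()
    rows = []
    for rec, ann in zip(bundle.records, bundle.annotations):
        carrier = sorted(rec.carriers)[0]
        row: dict[str, str] = {"ID": carrier}
        for col in ("Gender", "Age", "Morphology", "Site"):
            if col in meta.columns and carrier in meta.index:
                row[col] = str(meta.loc[carrier, col])
            elif col != "Site" or bundle.dialect == "european":
                row[col] = "NA"
        clinical = "/".join(x for x in (ann.clinvar if ann.clinvar in {"P", "LP"} else None,
                                        ann.hgmd if ann.hgmd == "DM" else None) if x)
        row.update({
            "Gene": rec.gene,
            "Chr": rec.chrom,
            "Location": str(rec.pos),
            "SNP IDS": rec.rsid or "",
            "REF": rec.ref,
            "VAR": rec.alt,
            "Variant Type": rec.printed_type or rec.variant_type.value,
            "Protein Change": rec.protein_change,
            "Variant Impact": rec.impact,
            "METASVM": ann.metasvm or "",
            "METALR": ann.metalr or "",
            "CADD": _fmt_num(ann.cadd_phred),
            "HGMD/ClinVar": clinical,
            f"gnomAD Exomes {population}": _fmt_maf(ann.maf_by_source.get(("gnomad_exomes", population))),
            f"gnomAD Genomes {population}": _fmt_maf(ann.maf_by_source.get(("gnomad_genomes", population))),
            "Pathway/Process": rec.pathway_label or "",
        })
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path: str | Path) -> CohortGenotypes:
    """Read a samples × variants dosage matrix (tab-separated).

    Expected layout: first column the sample identifier, a ``phenotype``
    column of 0/1 case indicators, and one column per variant named
    ``chrom|pos|ref|alt|gene`` with dosage entries 0/1/2 (-1 missing).
    The inverse of the matrix written by the ``simulate`` command.
    """
    import numpy as np

    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.ParserError) as exc:
        raise FixtureError(f"cannot load dosage matrix {path}: {exc}") from exc
    if "phenotype" not in df.columns:
        raise InputError(f"dosage matrix {path} lacks a 'phenotype' column")
    phenotype = df.pop("phenotype").astype(bool).to_numpy()
    sample_ids = [str(s) for s in df.index]
    records = []
    for col in df.columns:
        parts = str(col).split("|")
        if len(parts) != 5:
            raise InputError(f"variant column {col!r} is not 'chrom|pos|ref|alt|gene'")
        chrom, pos, ref, alt, gene = parts
        carriers = frozenset(s for s, d in zip(sample_ids, df[col]) if d > 0)
        records.append(
            VariantRecord(
                chrom=chrom, pos=int(pos), ref=ref, alt=alt, gene=gene,
                variant_type=VariantType.OTHER, carriers=carriers,
                observed=bool(carriers),
            )
        )
    return CohortGenotypes(
        sample_ids=sample_ids,
        phenotype=phenotype,
        dosage=df.to_numpy(dtype=np.int8),
        variant_index=records,
    )


def _fmt_num(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def _fmt_maf(x: float | None) -> str:
    if x is None:
        return ""
    if x == 0:
        return "0"
    return f"{x:.2e}"
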