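"""Optional VCF 4.x ingestion and export.

QC fields come from per-sample DP and allele-depth-derived heterozygous
allele balance (alt reads / total reads at heterozygous calls); caller
concordance is read from a configurable INFO key. Genotype dosages come
from GT. Reading goes through cyvcf2; writing emits a minimal single-block
text VCF suitable for round-tripping cohorts generated in-package.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .filters import QCFields
from .model import CohortGenotypes, VariantRecord, VariantType


def read_cohort_vcf(
    path: str | Path,
    phenotype: Mapping[str, bool],
    gene_map: Mapping[tuple[str, int, str, str], str] | None = None,
    caller_info_key: str = "CALLERS",
) -> tuple[CohortGenotypes, list[list[QCFields]]]:
    """Read genotype dosages and per-sample QC fields from a VCF.

    ``phenotype`` maps sample ID to case status and must cover every VCF
    sample. ``gene_map`` assigns (chrom, pos, ref, alt) to a gene symbol;
    when absent, the variant's ``GENE`` INFO field is used. Returns the
    cohort plus per-variant lists of per-sample QC fields (ABHet is None
    for non-heterozygous calls).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in phenotype]
    if missing:
        raise InputError(f"phenotype labels missing for sample(s) {missing[:5]}")

    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    qc_all: list[list[QCFields]] = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        gene = None
        if gene_map is not None:
            gene = gene_map.get((var.CHROM, var.POS, var.REF, alt))
        if gene is None:
            gene = var.INFO.get("GENE") or "UNKNOWN"
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=-1).astype(np.int8)
        carriers = frozenset(s for s, d in zip(samples, dosage) if d > 0)
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                gene=str(gene),
                variant_type=VariantType.OTHER,
                carriers=carriers,
                observed=bool(carriers),
            )
        )
        columns.append(dosage)

        def fmt(key):
            try:
                return var.format(key)
            except KeyError:
                return None

        depths = fmt("DP")
        ads = fmt("AD")
        callers = var.INFO.get(caller_info_key)
        per_sample = []
        for i, s in enumerate(samples):
            depth = int(depths[i][0]) if depths is not None and depths[i][0] >= 0 else 0
            abhet = None
            if gts[i] == 1 and ads is not None:
                ref_d, alt_d = (int(x) for x in ads[i][:2])
                total = ref_d + alt_d
                abhet = alt_d / total if total > 0 else None
            per_sample.append(
                QCFields(
                    read_depth=depth,
                    ab_het=abhet,
                    caller_count=int(callers) if callers is not None else 3,
                )
            )
        qc_all.append(per_sample)

    cohort = CohortGenotypes(
        sample_ids=samples,
        phenotype=[bool(phenotype[s]) for s in samples],
        dosage=np.column_stack(columns) if columns else np.zeros((len(samples), 0), dtype=np.int8),
        variant_index=records,
    )
    return cohort, qc_all


def write_cohort_vcf(cohort: CohortGenotypes, qc: Sequence[QCFields] | None, path: str | Path) -> None:
    """Write the cohort as an uncompressed VCF 4.2 with GT and DP."""
    contigs = sorted({rec.chrom for rec in cohort.variant_index})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.sample_ids),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for j, rec in enumerate(cohort.variant_index):
        depth = qc[j].read_depth if qc is not None else 30
        cells = [f"{gt_map[int(d)]}:{depth}" for d in cohort.dosage[:, j]]
        lines.append(
            "\t".join(
                [rec.chrom, str(rec.pos), rec.rsid or ".", rec.ref or "N", rec.alt or "N",
                 ".", "PASS", f"GENE={rec.gene}", "GT:DP"] + cells
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
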