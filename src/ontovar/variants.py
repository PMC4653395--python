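"""VCF parsing and variant filtering at transcript resolution.

The filtering stage cuts the candidate search space before any knowledge-based
scoring happens.  Four filter families are supported:

* **class** -- drop consequence classes usually deemed benign (synonymous
  substitutions, small in-frame indels, intronic/UTR variation).  Filtering is
  per *transcript*, not per gene: a variant that is synonymous in one
  transcript but missense in another survives (codon-position plurality).
* **region** -- keep only variants inside user intervals (e.g. from
  autozygosity mapping); 1-based, inclusive on both ends.
* **quality / allele frequency** -- minimum call quality and maximum
  population allele frequency; an absent AF annotation never removes a
  variant.
* **genotype** -- multi-sample inheritance logic.  In recessive mode a
  variant survives only if every affected sample is homozygous-alt or part of
  a candidate compound heterozygote (>= 2 retained heterozygous variants in
  the same gene) while no unaffected sample is; any explicit per-sample
  genotype combination can be required instead.

Consequences come from a configurable INFO field with comma-separated
``ALT|GENE|TRANSCRIPT|CLASS`` entries, or from a side-car TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ConsequenceClass",
    "Genotype",
    "VariantRecord",
    "FilterConfig",
    "InheritanceMode",
    "VcfData",
    "read_vcf",
    "load_consequence_tsv",
    "class_filter",
    "region_qual_af_filter",
    "genotype_filter",
    "apply_filters",
    "FilterReport",
    "write_vcf_subset",
    "write_filter_report",
    "DEFAULT_DROP_CLASSES",
]


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    INFRAME_INDEL = "INFRAME_INDEL"
    SPLICE = "SPLICE"
    INTRONIC = "INTRONIC"
    UTR = "UTR"
    OTHER = "OTHER"


#: classes commonly treated as benign and dropped by default
DEFAULT_DROP_CLASSES = frozenset(
    {ConsequenceClass.SYNONYMOUS, ConsequenceClass.INFRAME_INDEL,
     ConsequenceClass.INTRONIC, ConsequenceClass.UTR}
)


class Genotype(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class InheritanceMode(str, Enum):
    RECESSIVE = "RECESSIVE"
    DOMINANT = "DOMINANT"
    NONE = "NONE"


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    gene: str | None
    consequences: set[tuple[str, ConsequenceClass]]  # (transcript_id, class)
    genotypes: dict[str, Genotype]
    allele_frequency: float | None = None
    raw: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VcfData:
    records: list[VariantRecord]
    header: str
    samples: list[str]


def _recode_genotype(alleles: tuple[int | None, ...], alt_index: int) -> Genotype:
    """Per-alt-allele genotype for a multi-allelic row split on ``alt_index``."""
    if not alleles or any(a is None for a in alleles):
        return Genotype.MISSING
    n = sum(1 for a in alleles if a == alt_index)
    if n == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET if n > 0 else Genotype.HOM_REF


def _parse_csq(value: str | tuple[str, ...]) -> list[tuple[str, str, str, str]]:
    entries = value if isinstance(value, (tuple, list)) else str(value).split(",")
    parsed = []
    for entry in entries:
        parts = str(entry).split("|")
        if len(parts) != 4:
            raise ValueError(f"bad consequence entry {entry!r}")
        parsed.append(tuple(parts))  # (alt, gene, transcript, class)
    return parsed


def load_consequence_tsv(stream: IO[str] | str) -> dict[tuple[str, int, str, str], list[tuple[str, str, str]]]:
    """Side-car consequence table: chrom, pos, ref, alt, transcript, class, gene."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    table: dict[tuple[str, int, str, str], list[tuple[str, str, str]]] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        table.setdefault(key, []).append((row.transcript, getattr(row, "class"), row.gene))
    return table


def read_vcf(
    path: str,
    consequence_field: str = "CSQ",
    af_field: str = "AF",
    consequence_table: Mapping[tuple[str, int, str, str], list[tuple[str, str, str]]] | None = None,
) -> VcfData:
    """Read a VCF 4.x file into per-alt-allele variant records.

    Multi-allelic rows are split into one record per alt allele, with each
    sample's genotype recoded relative to that allele.  Records whose gene
    cannot be resolved are kept (they still pass site-level filters) but
    carry ``gene=None`` and are excluded from gene-level ranking.

    A VCF without a GT FORMAT field is a hard error; individual unparsable
    rows are logged and skipped.
    """
    vcf = pysam.VariantFile(path)
    if "GT" not in vcf.header.formats:
        raise ValueError("VCF has no GT FORMAT field")
    samples = list(vcf.header.samples)
    records: list[VariantRecord] = []
    for rec in vcf:
        try:
            records.extend(
                _split_record(rec, samples, consequence_field, af_field, consequence_table)
            )
        except (ValueError, KeyError) as exc:
            logger.warning("skipping unparsable row %s:%s (%s)", rec.chrom, rec.pos, exc)
    header = str(vcf.header)
    vcf.close()
    return VcfData(records, header, samples)


def _split_record(rec, samples, consequence_field, af_field, consequence_table):
    out = []
    alts = rec.alts or ()
    info_csq = None
    if consequence_table is None and consequence_field in rec.info:
        info_csq = _parse_csq(rec.info[consequence_field])
    afs = rec.info.get(af_field) if af_field in rec.info else None
    if afs is not None and not isinstance(afs, (tuple, list)):
        afs = (afs,)
    for i, alt in enumerate(alts):
        if alt == rec.ref:
            raise ValueError("ref == alt")
        genotypes = {
            s: _recode_genotype(tuple(rec.samples[s]["GT"]), i + 1) for s in samples
        }
        consequences: set[tuple[str, ConsequenceClass]] = set()
        gene = None
        entries: list[tuple[str, str, str]] = []
        if consequence_table is not None:
            entries = consequence_table.get((rec.chrom, rec.pos, rec.ref, alt), [])
        elif info_csq is not None:
            entries = [(tx, cls, g) for (a, g, tx, cls) in info_csq if a in (alt, "-")]
        for tx, cls, g in entries:
            consequences.add((tx, ConsequenceClass(cls)))
            gene = gene or g
        af = float(afs[i]) if afs is not None and i < len(afs) and afs[i] is not None else None
        out.append(
            VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                qual=rec.qual, gene=gene, consequences=consequences,
                genotypes=genotypes, allele_frequency=af, raw=str(rec).rstrip("\n"),
            )
        )
    return out


@dataclass
class FilterConfig:
    drop_classes: frozenset[ConsequenceClass] = frozenset()
    regions: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based inclusive
    min_qual: float | None = None
    max_af: float | None = None
    genotype_requirements: dict[str, set[Genotype]] = field(default_factory=dict)
    inheritance_mode: InheritanceMode = InheritanceMode.NONE
    affected: list[str] = field(default_factory=list)
    unaffected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if end < start:
                raise ValueError(f"degenerate region {chrom}:{start}-{end}")


def class_filter(v: VariantRecord, config: FilterConfig) -> bool:
    """Retain if any transcript consequence survives the dropped classes.

    Transcript plurality: benign in one transcript, damaging in another ->
    the variant survives.  A variant with no consequence annotation is kept
    (nothing marks it benign).
    """
    if not config.drop_classes or not v.consequences:
        return True
    return any(cls not in config.drop_classes for _, cls in v.consequences)


def region_qual_af_filter(v: VariantRecord, config: FilterConfig) -> bool:
    if config.regions:
        if not any(
            v.chrom == chrom and start <= v.pos <= end
            for chrom, start, end in config.regions
        ):
            return False
    if config.min_qual is not None and (v.qual is None or v.qual < config.min_qual):
        return False
    if config.max_af is not None and v.allele_frequency is not None:
        if v.allele_frequency > config.max_af:
            return False
    return True


def _recessive_ok(gt: Genotype, gene_het_count: int) -> bool:
    return gt is Genotype.HOM_ALT or (gt is Genotype.HET and gene_het_count >= 2)


def genotype_filter(
    v: VariantRecord,
    config: FilterConfig,
    gene_het_index: Mapping[tuple[str | None, str], int],
) -> bool:
    """Genotype/inheritance filter for one variant.

    ``gene_het_index`` maps (gene, sample) to the number of retained
    heterozygous variants that sample carries in that gene, which drives the
    compound-heterozygote logic (no phasing is attempted; two hets suffice).
    """
    for sample in list(config.genotype_requirements) + config.affected + config.unaffected:
        if sample not in v.genotypes:
            raise ValueError(f"sample {sample!r} named in filter config absent from VCF")

    if config.genotype_requirements:
        for sample, required in config.genotype_requirements.items():
            if v.genotypes[sample] not in required:
                return False

    if config.inheritance_mode is InheritanceMode.RECESSIVE:
        for s in config.affected:
            if not _recessive_ok(v.genotypes[s], gene_het_index.get((v.gene, s), 0)):
                return False
        for s in config.unaffected:
            if _recessive_ok(v.genotypes[s], gene_het_index.get((v.gene, s), 0)):
                return False
    elif config.inheritance_mode is InheritanceMode.DOMINANT:
        for s in config.affected:
            if v.genotypes[s] not in (Genotype.HET, Genotype.HOM_ALT):
                return False
        for s in config.unaffected:
            if v.genotypes[s] is not Genotype.HOM_REF:
                return False
    return True


@dataclass
class FilterReport:
    n_input: int = 0
    removed_class: int = 0
    removed_region_qual_af: int = 0
    removed_genotype: int = 0
    n_survivors: int = 0

    def total_removed(self) -> int:
        return self.removed_class + self.removed_region_qual_af + self.removed_genotype


def apply_filters(
    variants: Iterable[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], set[str], FilterReport]:
    """Run the full filter cascade.

    Order: class -> region/quality/AF -> genotype.  The genotype stage runs
    after the per-variant predicates so that compound-heterozygote counting
    only sees variants that survived them.  Returns the survivors, the set
    of candidate genes they map to, and per-stage removal counts.
    """
    variants = list(variants)
    report = FilterReport(n_input=len(variants))

    stage1 = [v for v in variants if class_filter(v, config)]
    report.removed_class = len(variants) - len(stage1)

    stage2 = [v for v in stage1 if region_qual_af_filter(v, config)]
    report.removed_region_qual_af = len(stage1) - len(stage2)

    het_index: dict[tuple[str | None, str], set[tuple]] = {}
    for v in stage2:
        for sample, gt in v.genotypes.items():
            if gt is Genotype.HET and v.gene is not None:
                het_index.setdefault((v.gene, sample), set()).add(v.key)
    het_counts = {k: len(keys) for k, keys in het_index.items()}

    survivors = [v for v in stage2 if genotype_filter(v, config, het_counts)]
    report.removed_genotype = len(stage2) - len(survivors)
    report.n_survivors = len(survivors)

    candidate_genes = {v.gene for v in survivors if v.gene is not None}
    return survivors, candidate_genes, report


def write_vcf_subset(data: VcfData, survivors: list[VariantRecord], path: str) -> None:
    """Write surviving variants as a valid VCF subset of the input."""
    keep = {v.raw for v in survivors}
    with open(path, "w") as fh:
        fh.write(data.header)
        for line in sorted(keep):
            fh.write(line + "\n")


def write_filter_report(report: FilterReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        fh.write(f"input\t{report.n_input}\n")
        fh.write(f"removed_class\t{report.removed_class}\n")
        fh.write(f"removed_region_qual_af\t{report.removed_region_qual_af}\n")
        fh.write(f"removed_genotype\t{report.removed_genotype}\n")
        fh.write(f"survivors\t{report.n_survivors}\n")
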