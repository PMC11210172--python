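"""Patient-specific somatic variants tracked as MRD biomarkers.

A diagnostic myeloid-panel variant becomes an MRD *marker* only if it passes
an eligibility policy: variants in clonal-hematopoiesis (CHIP) genes, in genes
recurrently mutated across myeloid neoplasias, or of uncertain significance
make poor residual-disease markers because they can persist in non-leukemic
clones. The policy here is configurable; the permissive default keeps genes of
variable significance (IDH1/IDH2/RUNX1/TP53) eligible, since such variants are
routinely tracked in practice, while a strict preset excludes them too.

Coordinates are 1-based inclusive genomic positions. Indel alleles follow a
trimmed convention: ``ref`` and ``alt`` share no redundant anchor base unless
the table provides them anchored (VCF input is left anchored but the insertion
offset is recorded so downstream sequence edits are unambiguous).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "MYELOID_PANEL_GENES",
    "VARIANT_CLASSES",
    "PATHOGENICITIES",
    "MarkerVariant",
    "EligibilityPolicy",
    "Eligibility",
    "MarkerValidationError",
    "MarkerTableError",
    "classify_marker_eligibility",
    "load_marker_table",
    "write_marker_table",
]

#: The 42-gene custom panel of genes frequently mutated in myeloid pathology.
MYELOID_PANEL_GENES = frozenset({
    "ASXL1", "BCOR", "BCORL1", "CALR", "CBL", "CSF3R", "CEBPA", "DNMT3A",
    "EPAS1", "EPOR", "ETV6", "EZH2", "FLT3", "IDH1", "IDH2", "JAK2",
    "KDM6A", "KIT", "KMT2A", "KRAS", "MPL", "NF1", "NPM1", "NRAS",
    "PHF6", "PRPF40B", "RAD21", "RUNX1", "SETBP1", "SF3A1", "SF3B1",
    "SH2B3", "SMC1A", "SRSF2", "STAG2", "TET2", "THPO", "TP53", "U2AF1",
    "VHL", "WT1", "ZRSR2",
})

VARIANT_CLASSES = frozenset({
    "missense", "nonsense", "frameshift", "non-frameshift indel",
    "splice", "synonymous", "other",
})
PATHOGENICITIES = frozenset({"pathogenic", "likely_pathogenic", "VUS"})

_DNA = frozenset("ACGT")


class MarkerValidationError(ValueError):
    """A marker variant violates a field invariant; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class MarkerTableError(ValueError):
    """A marker table could not be parsed; carries per-row errors."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {n}: {msg}" for n, msg in errors)
        super().__init__(f"{len(errors)} bad row(s): {lines}")


@dataclass(frozen=True)
class MarkerVariant:
    """One patient-specific somatic variant tracked as an MRD biomarker.

    ``pos`` is the 1-based genomic position of the first reference base
    affected. ``alt_allele`` may be empty (pure deletion); ``ref_allele``
    may not be empty unless the alt is non-empty (pure insertion).
    ``anchored`` records whether the alleles retain a shared VCF-style
    leading anchor base (set by the VCF reader).
    """

    patient_id: str
    gene: str
    hgvs_p: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str = "other"
    pathogenicity: str = "pathogenic"
    diagnostic_vaf: Optional[float] = None
    anchored: bool = False

    def __post_init__(self):
        self.validate()

    @property
    def marker_id(self) -> str:
        return f"{self.patient_id}:{self.gene}:{self.hgvs_p}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def validate(self) -> None:
        if not self.gene:
            raise MarkerValidationError("gene", "must be non-empty")
        if self.pos < 1:
            raise MarkerValidationError("pos", f"must be >= 1, got {self.pos}")
        for name, allele in (("ref_allele", self.ref_allele),
                             ("alt_allele", self.alt_allele)):
            if set(allele) - _DNA:
                raise MarkerValidationError(
                    name, f"contains non-ACGT characters: {allele!r}")
        if not self.ref_allele and not self.alt_allele:
            raise MarkerValidationError(
                "ref_allele", "ref and alt may not both be empty")
        if self.ref_allele == self.alt_allele:
            raise MarkerValidationError(
                "alt_allele", "ref and alt must differ")
        if self.variant_class not in VARIANT_CLASSES:
            raise MarkerValidationError(
                "variant_class", f"unknown class {self.variant_class!r}")
        if self.pathogenicity not in PATHOGENICITIES:
            raise MarkerValidationError(
                "pathogenicity", f"unknown value {self.pathogenicity!r}")
        if self.diagnostic_vaf is not None and not 0 <= self.diagnostic_vaf <= 1:
            raise MarkerValidationError(
                "diagnostic_vaf", f"must be in [0,1], got {self.diagnostic_vaf}")


@dataclass(frozen=True)
class EligibilityPolicy:
    """Which diagnostic variants may serve as MRD biomarkers.

    Rules are applied in a fixed order so the exclusion reason is
    deterministic: chip_gene, neoplasia_gene, variable_significance,
    pathogenicity, variant_class, specific_variant.
    """

    chip_genes: frozenset[str] = frozenset(
        {"DNMT3A", "ASXL1", "TET2", "SRSF2", "BCOR"})
    neoplasia_genes: frozenset[str] = frozenset(
        {"STAG2", "JAK2", "CALR", "MPL"})
    variable_significance_genes: frozenset[str] = frozenset(
        {"IDH1", "IDH2", "RUNX1", "TP53"})
    excluded_pathogenicity: frozenset[str] = frozenset({"VUS"})
    excluded_variant_classes: frozenset[str] = frozenset()
    exclude_variable_significance: bool = False
    exclude_specific_variants: frozenset[tuple[str, str]] = frozenset(
        {("DNMT3A", "p.Arg882His")})

    @classmethod
    def permissive(cls) -> "EligibilityPolicy":
        """The default: CHIP and pan-myeloid genes out, everything else in."""
        return cls()

    @classmethod
    def hasserjian_strict(cls) -> "EligibilityPolicy":
        """Strict preset: also drop variable-significance genes and the
        missense / non-frameshift classes."""
        return cls(
            exclude_variable_significance=True,
            excluded_variant_classes=frozenset(
                {"missense", "non-frameshift indel"}),
        )

    @classmethod
    def accept_all(cls) -> "EligibilityPolicy":
        return cls(chip_genes=frozenset(), neoplasia_genes=frozenset(),
                   variable_significance_genes=frozenset(),
                   excluded_pathogenicity=frozenset(),
                   exclude_specific_variants=frozenset())


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: Optional[str] = None  # chip_gene | neoplasia_gene | variable_significance | pathogenicity | variant_class | specific_variant

    def __bool__(self) -> bool:
        return self.eligible


def classify_marker_eligibility(
    variant: MarkerVariant,
    policy: EligibilityPolicy = EligibilityPolicy(),
) -> Eligibility:
    """Decide whether a diagnostic variant may serve as an MRD biomarker.

    Returns the FIRST matching exclusion rule (fixed order) as a
    machine-readable reason code, or an eligible decision. Pure function.
    """
    variant.validate()
    if variant.gene in policy.chip_genes:
        return Eligibility(False, "chip_gene")
    if variant.gene in policy.neoplasia_genes:
        return Eligibility(False, "neoplasia_gene")
    if (policy.exclude_variable_significance
            and variant.gene in policy.variable_significance_genes):
        return Eligibility(False, "variable_significance")
    if variant.pathogenicity in policy.excluded_pathogenicity:
        return Eligibility(False, "pathogenicity")
    if variant.variant_class in policy.excluded_variant_classes:
        return Eligibility(False, "variant_class")
    if (variant.gene, variant.hgvs_p) in policy.exclude_specific_variants:
        return Eligibility(False, "specific_variant")
    return Eligibility(True)


# ---------------------------------------------------------------------------
# Marker table I/O

_TSV_FIELDS = ["patient_id", "gene", "hgvs_p", "chrom", "pos", "ref", "alt",
               "variant_class", "pathogenicity", "diagnostic_vaf"]


def _row_to_variant(row: dict[str, str]) -> MarkerVariant:
    vaf_raw = (row.get("diagnostic_vaf") or "").strip()
    return MarkerVariant(
        patient_id=row["patient_id"].strip(),
        gene=row["gene"].strip(),
        hgvs_p=row["hgvs_p"].strip(),
        chrom=row["chrom"].strip(),
        pos=int(row["pos"]),
        ref_allele=row["ref"].strip().upper(),
        alt_allele=row["alt"].strip().upper(),
        variant_class=row["variant_class"].strip(),
        pathogenicity=row["pathogenicity"].strip(),
        diagnostic_vaf=float(vaf_raw) if vaf_raw not in ("", ".") else None,
    )


def _load_tsv(path: Path) -> tuple[list[MarkerVariant], list[tuple[int, str]]]:
    variants: list[MarkerVariant] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise MarkerTableError(
                [(1, f"header missing fields: {sorted(missing)}")])
        for lineno, row in enumerate(reader, start=2):
            try:
                variants.append(_row_to_variant(row))
            except (ValueError, KeyError) as exc:
                errors.append((lineno, str(exc)))
    return variants, errors


def _load_vcf(path: Path) -> tuple[list[MarkerVariant], list[tuple[int, str]]]:
    # INFO keys: SAMPLE (patient), GENE, HGVSP, VCLASS, PATH, DVAF (optional).
    # VCF alleles stay in anchored form; the anchor is recorded so amplicon
    # design can strip it (pos+1, drop shared leading base) for indels.
    import pysam

    variants: list[MarkerVariant] = []
    errors: list[tuple[int, str]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                info = rec.info
                alt = rec.alts[0] if rec.alts else ""
                # .get on a key missing from the ##INFO header raises
                dvaf = info.get("DVAF") if "DVAF" in info else None
                if isinstance(dvaf, tuple):
                    dvaf = dvaf[0]
                anchored = (len(rec.ref) != len(alt)
                            and len(rec.ref) >= 1 and len(alt) >= 1
                            and rec.ref[0] == alt[0])
                variants.append(MarkerVariant(
                    patient_id=str(info.get("SAMPLE", "NA")),
                    gene=str(info.get("GENE", "")),
                    hgvs_p=str(info.get("HGVSP", "")),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=str(alt).upper(),
                    variant_class=str(info.get("VCLASS", "other")),
                    pathogenicity=str(info.get("PATH", "pathogenic")),
                    diagnostic_vaf=float(dvaf) if dvaf is not None else None,
                    anchored=anchored,
                ))
            except (ValueError, KeyError) as exc:
                errors.append((rec.pos, str(exc)))
    return variants, errors


def load_marker_table(
    path: Union[str, Path],
    dialect: str = "tsv",
    strict: bool = True,
) -> list[MarkerVariant]:
    """Read a marker table (TSV or VCF 4.x) into :class:`MarkerVariant` rows.

    With ``strict`` (default) any unparseable row raises
    :class:`MarkerTableError` listing line numbers; otherwise bad rows are
    dropped silently after collection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        variants, errors = _load_tsv(path)
    elif dialect == "vcf":
        variants, errors = _load_vcf(path)
    else:
        raise ValueError(f"unknown marker table dialect: {dialect!r}")
    if errors and strict:
        raise MarkerTableError(errors)
    return variants


def write_marker_table(variants: Iterable[MarkerVariant],
                       path: Union[str, Path]) -> None:
    """Write markers as the canonical TSV (inverse of the tsv loader)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_FIELDS)
        for v in variants:
            writer.writerow([
                v.patient_id, v.gene, v.hgvs_p, v.chrom, v.pos,
                v.ref_allele, v.alt_allele, v.variant_class, v.pathogenicity,
                "" if v.diagnostic_vaf is None else repr(v.diagnostic_vaf),
            ])


def deanchor(variant: MarkerVariant) -> MarkerVariant:
    """Strip a shared VCF anchor base from an indel's alleles.

    ``chr4:106158216 C>CT`` becomes an insertion of ``T`` after position
    106158216, represented with ref ``""`` alt ``"T"`` at pos+1. SNVs and
    already-trimmed variants pass through unchanged.
    """
    ref, alt = variant.ref_allele, variant.alt_allele
    if not variant.anchored or not ref or not alt or ref[0] != alt[0]:
        return variant
    return replace(variant, pos=variant.pos + 1, ref_allele=ref[1:],
                   alt_allele=alt[1:], anchored=False)
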