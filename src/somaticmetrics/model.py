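"""Shared domain types for the somatic WES downstream pipeline.

Conventions
-----------
* Variant coordinates are 1-based (VCF/MAF convention).
* Region coordinates are 0-based half-open (BED convention).
* Variant allele fractions (VAFs) are stored as fractions in [0, 1];
  configuration thresholds named ``*_pct`` are expressed in percent and
  compared against ``100 * vaf``.
* Missing values are represented as ``None`` in memory and ``"."`` on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

VARIANT_TYPES = ("SNP", "INS", "DEL")
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "synonymous",
    "splice",
    "frameshift",
    "inframe_indel",
    "other",
)
REGION_CLASSES = ("exonic", "intronic", "UTR", "intergenic", "splicing")
POLYPHEN_CODES = ("B", "P", "D")  # benign / possibly damaging / probably damaging

#: The six pyrimidine-collapsed substitution classes, in display order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Transitions after pyrimidine-strand collapse.
TRANSITION_CLASSES = ("C>T", "T>C")


@dataclass
class VariantRecord:
    """One annotated somatic variant: the unit of filtering, spectrum, TMB and MATH.

    Annotation flags (``in_cosmic``, ``in_snp138``, PolyPhen-2 codes,
    ``popmax_af``, ``is_hotspot``, ``in_blacklist``) are consumed as input
    columns; annotation itself is out of scope.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNP / INS / DEL
    variant_class: str
    region_class: str
    gene: str
    depth: int
    alt_fwd: int
    alt_rev: int
    tumor_vaf: float
    control_vaf: float
    in_cosmic: bool = False
    in_snp138: bool = False
    polyphen_div: Optional[str] = None  # B/P/D or None for missing
    polyphen_var: Optional[str] = None
    popmax_af: Optional[float] = None  # ExAC/gnomAD popmax, None = missing
    is_hotspot: bool = False
    in_blacklist: bool = False

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.depth < 0 or self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"{self.sample_id}:{self.chrom}:{self.pos}: alt_fwd+alt_rev "
                f"({self.alt_fwd + self.alt_rev}) exceeds depth ({self.depth})"
            )
        if not (0.0 <= self.tumor_vaf <= 1.0 and 0.0 <= self.control_vaf <= 1.0):
            raise ValueError("VAFs must be fractions in [0, 1]")
        if self.popmax_af is not None and not (0.0 <= self.popmax_af <= 1.0):
            raise ValueError("popmax_af must be a fraction in [0, 1] or missing")
        for code in (self.polyphen_div, self.polyphen_var):
            if code is not None and code not in POLYPHEN_CODES:
                raise ValueError(f"unknown PolyPhen code {code!r}")
        if self.variant_type == "SNP":
            if (
                len(self.ref_allele) != 1
                or len(self.alt_allele) != 1
                or self.ref_allele == self.alt_allele
                or self.ref_allele not in "ACGT"
                or self.alt_allele not in "ACGT"
            ):
                raise ValueError(
                    f"SNP must have distinct single-base ACGT alleles, got "
                    f"{self.ref_allele!r}>{self.alt_allele!r}"
                )

    @property
    def alt_support(self) -> int:
        return self.alt_fwd + self.alt_rev


@dataclass
class FilterConfig:
    """Thresholds of the multi-criteria somatic SNV filter.

    Percent thresholds mirror how the rules are conventionally stated
    ("frequency >= 5" meaning 5%); VAFs in records stay fractional.
    """

    min_depth: int = 30
    min_hotspot_support: int = 5
    min_hotspot_control_vaf_pct: float = 1.0
    min_hotspot_tumor_vaf_pct: float = 5.0
    min_tumor_vaf_pct: float = 5.0
    min_support_reads: int = 5
    max_popmax_af: float = 0.001
    db_absence_excludes: bool = True
    exclude_nonsense: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_hotspot_support",
            "min_hotspot_control_vaf_pct",
            "min_hotspot_tumor_vaf_pct",
            "min_tumor_vaf_pct",
            "min_support_reads",
            "max_popmax_af",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StrLocusHistogram:
    """Read counts per detected allele length at one STR locus of one sample."""

    sample_id: str
    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, n in self.counts.items():
            if length <= 0:
                raise ValueError(f"allele length must be positive, got {length}")
            if n < 0:
                raise ValueError(f"read count must be non-negative, got {n}")

    @property
    def total_depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class RegionCount:
    """Read count over one captured target region (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    gc_fraction: float
    read_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SampleMetrics:
    """One sample's row in every cohort comparison.

    Missing metrics (input file absent, too few informative sites) are
    ``None``, never silent zeros.
    """

    sample_id: str
    tmb: Optional[float] = None
    math: Optional[float] = None
    msi_status: Optional[str] = None  # MSI-H / MSS / QNS
    n_gain: Optional[int] = None
    n_loss: Optional[int] = None
    cnv_burden: Optional[float] = None
    cni: Optional[float] = None


@dataclass
class CohortGroup:
    """A named set of samples (e.g. treatment-sensitive vs -insensitive)."""

    label: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError(f"group {self.label!r} is empty")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"group {self.label!r} has duplicate sample ids")


def pct(vaf: float) -> float:
    """Convert a fractional VAF to percent for threshold comparison."""
    return 100.0 * vaf
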