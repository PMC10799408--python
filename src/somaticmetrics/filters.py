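"""Multi-criteria somatic SNV filter with a hotspot rescue rule.

A variant is removed when it triggers at least one exclusion criterion; every
triggered criterion is evaluated and recorded (no short-circuit), so the
rejects carry a complete audit trail. Recurrent hotspot sites bypass only the
frequency/support criterion and are instead held to their own evidence
thresholds (alt support, matched-control VAF, tumor VAF).

Criteria that are undefined for indels (PolyPhen-2 codes, COSMIC/snp138 and
population-frequency lookups, which annotate substitutions) are skipped for
non-SNP records; depth, blacklist, region, gene, strand and frequency/support
apply to all records.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import FilterConfig, VariantRecord, pct

#: Removal reasons, in evaluation order.
FILTER_REASONS = (
    "low_depth",
    "blacklist",
    "intronic",
    "nonsense",
    "db_absent",
    "hla_or_none_gene",
    "polyphen_benign",
    "population_af",
    "strand_support",
    "vaf_support",
)


@dataclass
class FilterOutcome:
    """One variant's filter verdict with the complete list of triggered criteria."""

    variant: VariantRecord
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must hold exactly when no reason triggered")


def _evaluate(v: VariantRecord, cfg: FilterConfig) -> tuple[str, ...]:
    reasons: list[str] = []
    is_snp = v.variant_type == "SNP"

    if v.depth < cfg.min_depth:
        reasons.append("low_depth")
    if v.in_blacklist:
        reasons.append("blacklist")
    if v.region_class == "intronic":
        reasons.append("intronic")
    if cfg.exclude_nonsense and v.variant_class == "nonsense":
        reasons.append("nonsense")
    if is_snp and cfg.db_absence_excludes and not (v.in_cosmic or v.in_snp138):
        reasons.append("db_absent")
    if v.gene == "NONE" or v.gene.startswith("HLA"):
        reasons.append("hla_or_none_gene")
    if is_snp and v.polyphen_div == "B" and v.polyphen_var == "B":
        reasons.append("polyphen_benign")
    if is_snp and v.popmax_af is not None and v.popmax_af > cfg.max_popmax_af:
        reasons.append("population_af")
    if v.alt_fwd < 1 or v.alt_rev < 1:
        reasons.append("strand_support")

    if v.is_hotspot:
        ok = (
            v.alt_support >= cfg.min_hotspot_support
            and pct(v.control_vaf) >= cfg.min_hotspot_control_vaf_pct
            and pct(v.tumor_vaf) >= cfg.min_hotspot_tumor_vaf_pct
        )
    else:
        ok = (
            v.alt_support >= cfg.min_support_reads
            and pct(v.tumor_vaf) >= cfg.min_tumor_vaf_pct
        )
    if not ok:
        reasons.append("vaf_support")

    return tuple(reasons)


def apply_snv_filters(
    variants: list[VariantRecord], config: FilterConfig | None = None
) -> list[FilterOutcome]:
    """Apply every exclusion criterion to every variant, preserving input order.

    Returns one :class:`FilterOutcome` per input variant; ``kept`` is true
    exactly when no criterion triggered.
    """
    cfg = config or FilterConfig()
    return [
        FilterOutcome(variant=v, kept=not (r := _evaluate(v, cfg)), reasons=r)
        for v in variants
    ]


def kept_variants(outcomes: list[FilterOutcome]) -> list[VariantRecord]:
    """The surviving variants, in input order."""
    return [o.variant for o in outcomes if o.kept]
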