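"""Tumor mutational burden (TMB) and mutant-allele tumor heterogeneity (MATH).

TMB counts qualifying non-synonymous coding mutations and scales them to
mutations per megabase of targeted exonic sequence:

    TMB = n_candidates * 1e6 / exon_bases

MATH summarizes the dispersion of the tumor VAF distribution. Two styles are
provided:

* ``canonical`` (default): 100 * 1.4826 * MAD(v) / median(v), the literature
  statistic, where 1.4826 rescales the median absolute deviation to the
  standard deviation of a Gaussian;
* ``literal``: MAD(v) / median(v), the bare ratio without the percentage
  scaling or consistency constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import VariantRecord, pct

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD estimate the Gaussian SD.
MAD_CONSISTENCY = 1.4826

MATH_STYLES = ("canonical", "literal")


@dataclass
class TmbConfig:
    """Candidate-site thresholds and panel size for TMB."""

    exon_bases: int
    min_depth: int = 30
    min_vaf_pct: float = 5.0
    count_indels: bool = True

    def __post_init__(self) -> None:
        if self.exon_bases <= 0:
            raise ValueError("exon_bases must be positive")


@dataclass
class MathConfig:
    """VAF-selection rules and style for the MATH statistic.

    A mutation with tumor VAF below ``tumor_high_vaf_pct`` is retained only
    when its tumor VAF is at least ``low_vaf_ratio`` times the matched-control
    VAF — a guard against residual germline/contamination signal at low
    frequency.
    """

    min_vaf_pct: float = 5.0
    min_depth: int = 50
    exonic_only: bool = True
    drop_synonymous: bool = True
    tumor_high_vaf_pct: float = 10.0
    low_vaf_ratio: float = 10.0
    style: str = "canonical"

    def __post_init__(self) -> None:
        if self.style not in MATH_STYLES:
            raise ValueError(f"style must be one of {MATH_STYLES}")
        for name in ("min_vaf_pct", "min_depth", "tumor_high_vaf_pct", "low_vaf_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def compute_tmb(variants: Sequence[VariantRecord], config: TmbConfig) -> float:
    """Mutations per megabase from filtered variants of one sample.

    Candidates are exonic, non-synonymous SNVs (and indels when
    ``count_indels``) meeting the depth and VAF thresholds.
    """
    n = 0
    for v in variants:
        if v.region_class != "exonic" or v.variant_class == "synonymous":
            continue
        if v.variant_type != "SNP" and not config.count_indels:
            continue
        if v.depth < config.min_depth or pct(v.tumor_vaf) < config.min_vaf_pct:
            continue
        n += 1
    return n * 1e6 / config.exon_bases


def select_math_vafs(
    variants: Sequence[VariantRecord], config: MathConfig | None = None
) -> list[float]:
    """Tumor VAFs entering the MATH statistic for one sample.

    Keeps SNVs meeting VAF/depth/region/class thresholds; of those, VAFs below
    the high-confidence cut must additionally exceed ``low_vaf_ratio`` times
    the matched-control VAF.
    """
    cfg = config or MathConfig()
    vafs: list[float] = []
    for v in variants:
        if v.variant_type != "SNP":
            continue
        if pct(v.tumor_vaf) < cfg.min_vaf_pct or v.depth < cfg.min_depth:
            continue
        if cfg.exonic_only and v.region_class != "exonic":
            continue
        if cfg.drop_synonymous and v.variant_class == "synonymous":
            continue
        if pct(v.tumor_vaf) < cfg.tumor_high_vaf_pct:
            if v.tumor_vaf < cfg.low_vaf_ratio * v.control_vaf:
                continue
        vafs.append(v.tumor_vaf)
    return vafs


def compute_math(
    vafs: Sequence[float], style: str = "canonical"
) -> Optional[float]:
    """MATH value of a VAF list, or ``None`` when undefined.

    Undefined for fewer than two VAFs or a zero median (logged).
    """
    if style not in MATH_STYLES:
        raise ValueError(f"style must be one of {MATH_STYLES}")
    if len(vafs) < 2:
        return None
    arr = np.asarray(vafs, dtype=float)
    med = float(np.median(arr))
    if med == 0.0:
        logger.warning("median VAF is zero; MATH undefined")
        return None
    mad = float(np.median(np.abs(arr - med)))
    ratio = mad / med
    if style == "literal":
        return ratio
    return 100.0 * MAD_CONSISTENCY * ratio
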