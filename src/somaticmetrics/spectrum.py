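"""Six-class mutation spectrum, variant tallies, and transition/transversion tests.

Every SNV is collapsed onto the pyrimidine strand (the COSMIC/maftools
convention): a substitution whose reference base is a purine is replaced by
its reverse complement, so the twelve ordered base pairs map onto six classes
C>A, C>G, C>T, T>A, T>C, T>G. Transitions are C>T and T>C; the other four
classes are transversions. Under a uniform spectrum the null transition
proportion is therefore 1/3 (2 of 6 classes).

The within-sample TiTv imbalance test is an exact two-sided binomial test of
the transition count against that 1/3 null; the between-group test is a
rank-sum test on per-sample transition fractions. Group-level class
proportions are pooled counts over pooled totals (matching stacked-bar
summaries), while significance tests always operate on per-sample values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import scipy.stats as st

from .stats import exact_rank_sum_p
from .model import (
    SUBSTITUTION_CLASSES,
    TRANSITION_CLASSES,
    VARIANT_CLASSES,
    VARIANT_TYPES,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Null transition proportion among the six collapsed classes.
NULL_TI_PROPORTION = 1.0 / 3.0


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """Collapse a single-base substitution onto the pyrimidine strand.

    >>> classify_substitution("G", "A")
    'C>T'
    """
    if ref_allele not in _COMPLEMENT or alt_allele not in _COMPLEMENT:
        raise ValueError(f"alleles must be single bases in ACGT, got "
                         f"{ref_allele!r}>{alt_allele!r}")
    if ref_allele == alt_allele:
        raise ValueError(f"ref and alt must differ, got {ref_allele!r}")
    if ref_allele in "AG":  # purine reference: complement both strands
        ref_allele = _COMPLEMENT[ref_allele]
        alt_allele = _COMPLEMENT[alt_allele]
    return f"{ref_allele}>{alt_allele}"


@dataclass
class SpectrumSummary:
    """Per-sample substitution-class, variant-classification and type tallies."""

    sample_id: str
    class_counts: dict[str, int]
    classification_counts: dict[str, int]
    type_counts: dict[str, int]

    @property
    def ti_count(self) -> int:
        return sum(self.class_counts[c] for c in TRANSITION_CLASSES)

    @property
    def tv_count(self) -> int:
        return sum(
            self.class_counts[c]
            for c in SUBSTITUTION_CLASSES
            if c not in TRANSITION_CLASSES
        )

    @property
    def n_snv(self) -> int:
        return sum(self.class_counts.values())

    @property
    def ti_fraction(self) -> Optional[float]:
        n = self.n_snv
        return self.ti_count / n if n else None

    def class_proportions(self) -> Optional[dict[str, float]]:
        n = self.n_snv
        if n == 0:
            return None
        return {c: self.class_counts[c] / n for c in SUBSTITUTION_CLASSES}


def summarize_spectrum(variants: Sequence[VariantRecord]) -> SpectrumSummary:
    """Tally one sample's spectrum. Only SNPs enter the six-class counts;
    all records enter the classification and type tallies."""
    samples = {v.sample_id for v in variants}
    if len(samples) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(samples)}")
    sample_id = samples.pop() if samples else ""

    class_counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    classification_counts = dict.fromkeys(VARIANT_CLASSES, 0)
    type_counts = dict.fromkeys(VARIANT_TYPES, 0)
    for v in variants:
        classification_counts[v.variant_class] += 1
        type_counts[v.variant_type] += 1
        if v.variant_type == "SNP":
            class_counts[classify_substitution(v.ref_allele, v.alt_allele)] += 1
    return SpectrumSummary(sample_id, class_counts, classification_counts, type_counts)


def titv_imbalance_test(summary: SpectrumSummary) -> Optional[float]:
    """Exact two-sided binomial p-value for transition excess/deficit.

    Tests ti_count successes in ti+tv trials against the null proportion 1/3.
    Returns ``None`` for a sample without SNVs.
    """
    n = summary.n_snv
    if n == 0:
        return None
    return float(st.binomtest(summary.ti_count, n, NULL_TI_PROPORTION).pvalue)


def _ranksum_p(a: Sequence[float], b: Sequence[float]) -> Optional[float]:
    """Exact two-sided rank-sum p (tie-aware); None below 2 per group."""
    if len(a) < 2 or len(b) < 2:
        return None
    return exact_rank_sum_p(a, b)


@dataclass
class SpectrumComparison:
    """Between-group spectrum contrast: pooled proportions + per-sample tests."""

    group_a: str
    group_b: str
    per_class_stats: dict[str, tuple[float, float, Optional[float]]]
    titv_p: Optional[float]
    dominant_class_a: str = ""
    dominant_class_b: str = ""


def compare_group_spectra(
    summaries_a: Sequence[SpectrumSummary],
    summaries_b: Sequence[SpectrumSummary],
    label_a: str = "A",
    label_b: str = "B",
) -> SpectrumComparison:
    """Contrast six-class proportions and Ti fractions between two groups.

    Pooled proportions describe each group; rank-sum tests on per-sample
    proportions assess each class and the Ti fraction. Samples without SNVs
    are dropped from the tests with a warning.
    """
    if not summaries_a or not summaries_b:
        raise ValueError("both groups must be non-empty")

    def informative(summaries: Sequence[SpectrumSummary]) -> list[SpectrumSummary]:
        kept = [s for s in summaries if s.n_snv > 0]
        for s in summaries:
            if s.n_snv == 0:
                logger.warning(
                    "sample %s has no SNVs; dropped from proportion tests", s.sample_id
                )
        return kept

    inf_a, inf_b = informative(summaries_a), informative(summaries_b)

    def pooled(summaries: Sequence[SpectrumSummary]) -> dict[str, float]:
        totals = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
        for s in summaries:
            for c in SUBSTITUTION_CLASSES:
                totals[c] += s.class_counts[c]
        grand = sum(totals.values())
        return {c: (totals[c] / grand if grand else 0.0) for c in SUBSTITUTION_CLASSES}

    pooled_a, pooled_b = pooled(summaries_a), pooled(summaries_b)

    per_class: dict[str, tuple[float, float, Optional[float]]] = {}
    for c in SUBSTITUTION_CLASSES:
        props_a = [s.class_counts[c] / s.n_snv for s in inf_a]
        props_b = [s.class_counts[c] / s.n_snv for s in inf_b]
        per_class[c] = (pooled_a[c], pooled_b[c], _ranksum_p(props_a, props_b))

    titv_p = _ranksum_p(
        [s.ti_fraction for s in inf_a], [s.ti_fraction for s in inf_b]
    )

    def dominant(props: dict[str, float]) -> str:
        return max(SUBSTITUTION_CLASSES, key=lambda c: props[c])

    return SpectrumComparison(
        group_a=label_a,
        group_b=label_b,
        per_class_stats=per_class,
        titv_p=titv_p,
        dominant_class_a=dominant(pooled_a),
        dominant_class_b=dominant(pooled_b),
    )
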