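"""Cohort assembly: per-sample metrics, group contrasts, and the report.

Group tests are intentionally assumption-light because cohorts of this kind
are tiny (a handful of samples per arm): continuous metrics are compared
with a two-sided Mann-Whitney rank-sum test (exact when sample sizes allow),
MSI status with Fisher's exact test on the 2x2 table of MSI-H vs not.
P-values are reported raw, with no multiple-testing correction, alongside
medians and IQRs — they are descriptive companions to the effect direction,
not confirmatory claims.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as st

from .burden import MathConfig, TmbConfig, compute_math, compute_tmb, select_math_vafs
from .copynumber import analyze_sample
from .filters import apply_snv_filters, kept_variants
from .model import CohortGroup, FilterConfig, SampleMetrics, StrLocusHistogram, RegionCount, VariantRecord
from .msi import MsiBaseline, call_sample
from .stats import exact_rank_sum_p, rank_sum_statistic
from .spectrum import SpectrumComparison, SpectrumSummary, compare_group_spectra, summarize_spectrum

logger = logging.getLogger(__name__)

CONTINUOUS_METRICS = ("tmb", "math", "cnv_burden", "cni")

#: Minimal schema of the machine-readable report (checked by validate_report).
REPORT_SCHEMA = {
    "metrics": list,  # one object per sample
    "comparisons": list,
    "spectrum_comparisons": list,
    "notes": list,
}


@dataclass
class GroupComparison:
    """One metric contrasted between two named groups."""

    metric: str
    group_a: str
    group_b: str
    summary_a: dict
    summary_b: dict
    statistic: Optional[float]
    p_value: Optional[float]

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def collect_metrics(
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    sample_ids: Sequence[str],
    tmb_config: TmbConfig,
    math_config: MathConfig | None = None,
    filter_config: FilterConfig | None = None,
    str_by_sample: Optional[Mapping[str, Sequence[StrLocusHistogram]]] = None,
    msi_baseline: Optional[MsiBaseline] = None,
    region_tumors: Optional[Mapping[str, Sequence[RegionCount]]] = None,
    region_panel: Optional[Mapping[str, Sequence[RegionCount]]] = None,
) -> list[SampleMetrics]:
    """One :class:`SampleMetrics` row per sample, running the full pipeline.

    Variants are filtered first; TMB and MATH use the kept set. Samples
    missing an input modality get ``None`` in the corresponding fields with a
    warning — never silent zeros.
    """
    if not sample_ids:
        raise ValueError("no samples")
    math_config = math_config or MathConfig()
    rows: list[SampleMetrics] = []
    for sid in sample_ids:
        m = SampleMetrics(sample_id=sid)
        if sid in variants_by_sample:
            kept = kept_variants(
                apply_snv_filters(list(variants_by_sample[sid]), filter_config)
            )
            m.tmb = compute_tmb(kept, tmb_config)
            m.math = compute_math(select_math_vafs(kept, math_config), math_config.style)
        else:
            logger.warning("sample %s has no variant table; TMB/MATH missing", sid)
        if str_by_sample is not None and msi_baseline is not None and sid in str_by_sample:
            m.msi_status = call_sample(list(str_by_sample[sid]), msi_baseline, sid).status
        else:
            logger.warning("sample %s has no STR data; MSI status missing", sid)
        if region_tumors is not None and region_panel is not None and sid in region_tumors:
            profile, cni = analyze_sample(list(region_tumors[sid]), region_panel)
            m.n_gain, m.n_loss = profile.n_gain, profile.n_loss
            m.cnv_burden, m.cni = profile.burden, cni.cni
        else:
            logger.warning("sample %s has no region counts; CNV/CNI missing", sid)
        rows.append(m)
    return rows


def _summary(values: Sequence[float]) -> dict:
    if not values:
        return {"n": 0, "median": None, "iqr": None}
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return {"n": len(values), "median": float(np.median(arr)), "iqr": [float(q1), float(q3)]}


def compare_groups(
    metrics: Sequence[SampleMetrics],
    group_a: CohortGroup,
    group_b: CohortGroup,
    metric: str,
) -> GroupComparison:
    """Contrast one metric between two groups.

    Continuous metrics use a two-sided rank-sum test on per-sample values
    (missing values dropped with a warning); ``msi_status`` uses Fisher's
    exact test on MSI-H vs not counts.
    """
    by_id = {m.sample_id: m for m in metrics}

    def members(group: CohortGroup) -> list[SampleMetrics]:
        return [by_id[sid] for sid in group.sample_ids if sid in by_id]

    a, b = members(group_a), members(group_b)
    if not a or not b:
        raise ValueError("both groups need at least one sample with metrics")

    if metric == "msi_status":
        def counts(rows: list[SampleMetrics]) -> tuple[int, int]:
            called = [m.msi_status for m in rows if m.msi_status is not None]
            high = sum(1 for s in called if s == "MSI-H")
            return high, len(called) - high
        ha, oa = counts(a)
        hb, ob = counts(b)
        if (ha + oa) == 0 or (hb + ob) == 0:
            logger.warning("a group has no MSI calls for %s vs %s", group_a.label, group_b.label)
            stat, p = None, None
        else:
            res = st.fisher_exact([[ha, oa], [hb, ob]])
            stat, p = float(res.statistic), float(res.pvalue)
        return GroupComparison(
            metric, group_a.label, group_b.label,
            {"msi_h": ha, "other": oa}, {"msi_h": hb, "other": ob}, stat, p,
        )

    if metric not in CONTINUOUS_METRICS:
        raise ValueError(f"unknown metric {metric!r}")

    def values(rows: list[SampleMetrics], label: str) -> list[float]:
        vals = [getattr(m, metric) for m in rows]
        missing = sum(1 for v in vals if v is None)
        if missing:
            logger.warning(
                "%d sample(s) in %s missing %s; dropped from test", missing, label, metric
            )
        return [float(v) for v in vals if v is not None]

    va, vb = values(a, group_a.label), values(b, group_b.label)
    if not va or not vb:
        logger.warning("group entirely missing %s; p-value missing", metric)
        stat, p = None, None
    else:
        stat = rank_sum_statistic(va, vb)
        p = exact_rank_sum_p(va, vb)
    return GroupComparison(
        metric, group_a.label, group_b.label, _summary(va), _summary(vb), stat, p
    )


def _metrics_frame(metrics: Sequence[SampleMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "tmb": m.tmb,
                "math": m.math,
                "msi_status": m.msi_status,
                "n_gain": m.n_gain,
                "n_loss": m.n_loss,
                "cnv_burden": m.cnv_burden,
                "cni": m.cni,
            }
            for m in metrics
        ]
    )


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "metric": c.metric,
        "group_a": c.group_a,
        "group_b": c.group_b,
        "summary_a": c.summary_a,
        "summary_b": c.summary_b,
        "statistic": c.statistic,
        "p_value": c.p_value,
    }


def _spectrum_comparison_dict(s: SpectrumComparison) -> dict:
    return {
        "group_a": s.group_a,
        "group_b": s.group_b,
        "dominant_class_a": s.dominant_class_a,
        "dominant_class_b": s.dominant_class_b,
        "titv_p": s.titv_p,
        "per_class": {
            cls: {"proportion_a": pa, "proportion_b": pb, "p_value": p}
            for cls, (pa, pb, p) in s.per_class_stats.items()
        },
    }


def validate_report(payload: dict) -> None:
    """Check the machine-readable report against the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(f"report key {key!r} is not a {typ.__name__}")
    for row in payload["metrics"]:
        if "sample_id" not in row:
            raise ValueError("metrics row missing sample_id")


def render_report(
    metrics: Sequence[SampleMetrics],
    comparisons: Sequence[GroupComparison],
    spectrum_comparisons: Sequence[SpectrumComparison],
    out_dir: Union[str, Path],
    groups: Sequence[CohortGroup] = (),
) -> dict:
    """Write the JSON report, TSV tables, and a human-readable summary.

    Returns the JSON payload. The summary names, per contrast, the dominant
    substitution class of each group, the TiTv test p-value, MSI-H counts,
    and metric medians.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload = {
        "metrics": _metrics_frame(metrics).to_dict("records"),
        "comparisons": [_comparison_dict(c) for c in comparisons],
        "spectrum_comparisons": [_spectrum_comparison_dict(s) for s in spectrum_comparisons],
        "notes": [
            "p-values are raw (no multiple-testing correction) and descriptive; "
            "group sizes are small"
        ],
    }
    validate_report(payload)
    (out / "report.json").write_text(json.dumps(payload, indent=2))

    _metrics_frame(metrics).to_csv(out / "metrics.tsv", sep="\t", index=False)
    if comparisons:
        pd.DataFrame([_comparison_dict(c) for c in comparisons]).to_csv(
            out / "comparisons.tsv", sep="\t", index=False
        )

    lines = ["Cohort report", "============", ""]
    if groups:
        for g in groups:
            lines.append(f"group {g.label}: {len(g.sample_ids)} samples")
        lines.append("")
    for s in spectrum_comparisons:
        titv = "NA" if s.titv_p is None else f"{s.titv_p:.4g}"
        lines.append(
            f"{s.group_a} vs {s.group_b}: dominant class {s.dominant_class_a} vs "
            f"{s.dominant_class_b}; TiTv rank-sum p = {titv}"
        )
    for c in comparisons:
        if c.metric == "msi_status":
            lines.append(
                f"{c.metric} {c.group_a} vs {c.group_b}: MSI-H "
                f"{c.summary_a['msi_h']}/{c.summary_a['msi_h'] + c.summary_a['other']} vs "
                f"{c.summary_b['msi_h']}/{c.summary_b['msi_h'] + c.summary_b['other']}; "
                f"Fisher p = {'NA' if c.p_value is None else f'{c.p_value:.4g}'}"
            )
        else:
            med_a = c.summary_a.get("median")
            med_b = c.summary_b.get("median")
            fmt = lambda x: "NA" if x is None else f"{x:.4g}"
            lines.append(
                f"{c.metric} {c.group_a} vs {c.group_b}: median {fmt(med_a)} vs "
                f"{fmt(med_b)}; rank-sum p = {'NA' if c.p_value is None else f'{c.p_value:.4g}'}"
            )
    lines.append("")
    lines.append(payload["notes"][0])
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return payload


def run_cohort_analysis(
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    groups: Sequence[CohortGroup],
    tmb_config: TmbConfig,
    out_dir: Optional[Union[str, Path]] = None,
    **collect_kwargs,
) -> tuple[list[SampleMetrics], list[GroupComparison], list[SpectrumComparison]]:
    """End-to-end cohort pass: metrics, pairwise group contrasts, optional report.

    Contrasts are computed for every ordered pair of consecutive groups
    (typical use: exactly two groups).
    """
    sample_ids = [sid for g in groups for sid in g.sample_ids]
    metrics = collect_metrics(
        variants_by_sample, sample_ids, tmb_config, **collect_kwargs
    )

    filter_config = collect_kwargs.get("filter_config")
    summaries: dict[str, SpectrumSummary] = {}
    for sid in sample_ids:
        if sid in variants_by_sample:
            kept = kept_variants(
                apply_snv_filters(list(variants_by_sample[sid]), filter_config)
            )
            summaries[sid] = summarize_spectrum(kept)

    comparisons: list[GroupComparison] = []
    spectrum_comparisons: list[SpectrumComparison] = []
    for ga, gb in zip(groups, groups[1:]):
        for metric in (*CONTINUOUS_METRICS, "msi_status"):
            comparisons.append(compare_groups(metrics, ga, gb, metric))
        spectrum_comparisons.append(
            compare_group_spectra(
                [summaries[s] for s in ga.sample_ids if s in summaries],
                [summaries[s] for s in gb.sample_ids if s in summaries],
                ga.label,
                gb.label,
            )
        )
    if out_dir is not None:
        render_report(metrics, comparisons, spectrum_comparisons, out_dir, groups)
    return metrics, comparisons, spectrum_comparisons
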