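"""Microsatellite instability (MSI) calling from STR allele-length histograms.

The caller works at the level of detectable allele counts per short tandem
repeat (STR) locus:

1. **Allele QC** — a locus is evaluable only with sequencing depth > 100x;
   allele lengths need >= 2 supporting reads and a frequency of at least 5%
   of the most-supported allele.
2. **Baseline** — from a panel of non-tumor samples, the per-locus mean and
   sample (n-1) standard deviation of the number of detectable alleles.
3. **Locus call** — a tumor locus is *unstable* when its allele count
   strictly exceeds mean + 4*SD of the baseline, otherwise *stable*; loci
   failing QC or absent from the baseline are *not evaluable*.
4. **Sample call** — MSI-H with >= 2 unstable loci; otherwise MSS with >= 4
   stable loci; otherwise QNS (quantity not sufficient). When both thresholds
   are met, instability evidence dominates (MSI-H).
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .model import StrLocusHistogram

logger = logging.getLogger(__name__)

MSI_HIGH = "MSI-H"
MSI_STABLE = "MSS"
MSI_QNS = "QNS"

DEFAULT_MIN_DEPTH = 100
DEFAULT_MIN_ALLELE_READS = 2
DEFAULT_MIN_TOP_FRACTION = 0.05
UNSTABLE_SD_MULTIPLIER = 4.0
MIN_UNSTABLE_FOR_MSI_H = 2
MIN_STABLE_FOR_MSS = 4


def filter_alleles(
    hist: StrLocusHistogram,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_reads: int = DEFAULT_MIN_ALLELE_READS,
    min_top_fraction: float = DEFAULT_MIN_TOP_FRACTION,
) -> Optional[set[int]]:
    """Detectable allele lengths at one locus, or ``None`` when not evaluable.

    Not evaluable when total depth <= ``min_depth`` (the rule is strict:
    depth must exceed 100x). Kept lengths need ``min_allele_reads`` reads and
    at least ``min_top_fraction`` of the top allele's reads.
    """
    if hist.total_depth <= min_depth:
        return None
    top = max(hist.counts.values(), default=0)
    return {
        length
        for length, n in hist.counts.items()
        if n >= min_allele_reads and n >= min_top_fraction * top
    }


@dataclass
class BaselineLocus:
    mean_allele_count: float
    sd_allele_count: float
    n_panel: int


@dataclass
class MsiBaseline:
    """Per-locus allele-count mean/SD from the normal panel."""

    loci: dict[str, BaselineLocus]

    def threshold(self, locus_id: str) -> float:
        entry = self.loci[locus_id]
        return entry.mean_allele_count + UNSTABLE_SD_MULTIPLIER * entry.sd_allele_count

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            locus: {
                "mean_allele_count": e.mean_allele_count,
                "sd_allele_count": e.sd_allele_count,
                "n_panel": e.n_panel,
            }
            for locus, e in self.loci.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MsiBaseline":
        payload = json.loads(Path(path).read_text())
        return cls(
            {locus: BaselineLocus(**entry) for locus, entry in payload.items()}
        )


def build_baseline(
    panel: Mapping[str, Sequence[StrLocusHistogram]],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_reads: int = DEFAULT_MIN_ALLELE_READS,
    min_top_fraction: float = DEFAULT_MIN_TOP_FRACTION,
) -> MsiBaseline:
    """Per-locus baseline from a panel of non-tumor samples.

    Loci evaluable in fewer than two panel samples are dropped with a
    warning; an empty panel is an error.
    """
    if not panel:
        raise ValueError("panel is empty")
    counts_by_locus: dict[str, list[int]] = {}
    for sample_id, hists in panel.items():
        for hist in hists:
            alleles = filter_alleles(hist, min_depth, min_allele_reads, min_top_fraction)
            if alleles is None:
                continue
            counts_by_locus.setdefault(hist.locus_id, []).append(len(alleles))

    loci: dict[str, BaselineLocus] = {}
    for locus_id, counts in counts_by_locus.items():
        if len(counts) < 2:
            logger.warning(
                "locus %s evaluable in only %d panel sample(s); dropped from baseline",
                locus_id,
                len(counts),
            )
            continue
        loci[locus_id] = BaselineLocus(
            mean_allele_count=statistics.mean(counts),
            sd_allele_count=statistics.stdev(counts),
            n_panel=len(counts),
        )
    return MsiBaseline(loci)


@dataclass
class MsiLocusCall:
    locus_id: str
    allele_count: Optional[int]
    status: str  # unstable / stable / not_evaluable

    def __post_init__(self) -> None:
        if (self.status == "not_evaluable") != (self.allele_count is None):
            raise ValueError("not_evaluable exactly when allele_count is missing")


def call_locus(
    hist: StrLocusHistogram,
    baseline: MsiBaseline,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_reads: int = DEFAULT_MIN_ALLELE_READS,
    min_top_fraction: float = DEFAULT_MIN_TOP_FRACTION,
) -> MsiLocusCall:
    """Stability call for one tumor locus against the baseline.

    Unstable when the allele count strictly exceeds mean + 4*SD; loci absent
    from the baseline or failing QC are not evaluable.
    """
    if hist.locus_id not in baseline.loci:
        logger.warning("locus %s absent from baseline; not evaluable", hist.locus_id)
        return MsiLocusCall(hist.locus_id, None, "not_evaluable")
    alleles = filter_alleles(hist, min_depth, min_allele_reads, min_top_fraction)
    if alleles is None:
        return MsiLocusCall(hist.locus_id, None, "not_evaluable")
    n = len(alleles)
    status = "unstable" if n > baseline.threshold(hist.locus_id) else "stable"
    return MsiLocusCall(hist.locus_id, n, status)


@dataclass
class MsiSampleCall:
    sample_id: str
    locus_calls: list[MsiLocusCall]
    n_unstable: int
    n_stable: int
    status: str  # MSI-H / MSS / QNS


def classify_sample(
    locus_calls: Sequence[MsiLocusCall], sample_id: str = ""
) -> MsiSampleCall:
    """Sample-level MSI status from per-locus calls.

    MSI-H with >= 2 unstable loci (instability dominates); else MSS with
    >= 4 stable loci; else QNS.
    """
    if not locus_calls:
        raise ValueError("at least one locus call required")
    n_unstable = sum(1 for c in locus_calls if c.status == "unstable")
    n_stable = sum(1 for c in locus_calls if c.status == "stable")
    if n_unstable >= MIN_UNSTABLE_FOR_MSI_H:
        status = MSI_HIGH
    elif n_stable >= MIN_STABLE_FOR_MSS:
        status = MSI_STABLE
    else:
        status = MSI_QNS
    return MsiSampleCall(sample_id, list(locus_calls), n_unstable, n_stable, status)


def call_sample(
    hists: Sequence[StrLocusHistogram],
    baseline: MsiBaseline,
    sample_id: str = "",
    **qc_kwargs,
) -> MsiSampleCall:
    """Convenience wrapper: per-locus calls + sample classification."""
    calls = [call_locus(h, baseline, **qc_kwargs) for h in hists]
    sid = sample_id or (hists[0].sample_id if hists else "")
    return classify_sample(calls, sid)
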