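"""Region-level copy-number calls and the copy-number instability (CNI) score.

Pipeline, per tumor sample, against a panel of normal samples sharing the
same target-region grid:

1. **GC/length correction** — per-region read rates (count / region length)
   are divided by the median rate of their 2% GC bin and rescaled by the
   global median rate; bins with fewer than 5 regions fall back to the global
   median (no GC correction there).
2. **log2 ratios** — log2((tumor + eps) / (panel mean + eps)) per region,
   with a half-read-equivalent epsilon guarding zero counts. Panel members
   get leave-one-out ratios (each against the mean of the others) so their
   spread is not deflated by self-reference.
3. **Z-scores** — per region, (tumor_log2 - panel mean) / panel SD, with the
   SD floored at 1e-6 (a constant panel region makes any deviation a huge
   |z|; such regions are logged).
4. **Retention threshold** — per region, the 95th percentile of the panel's
   own z-scores plus twice their standard deviation (a pooled global
   threshold is available as an option).
5. **CNI score** — the sum of tumor z-scores strictly above threshold
   (one-sided by default; a two-sided option retains |z| exceedances so
   deletions can contribute).

Copy-number gain/loss calls use CN = 2 * 2^log2 (diploid autosome
assumption): CN strictly above 4 is a gain, strictly below 1.2 a loss,
boundary values neutral. Quantiles use linear interpolation between order
statistics throughout, so results are bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import RegionCount

logger = logging.getLogger(__name__)

GAIN_THRESHOLD = 4.0
LOSS_THRESHOLD = 1.2
GC_BIN_WIDTH = 0.02
MIN_REGIONS_PER_GC_BIN = 5
SD_FLOOR = 1e-6
PANEL_QUANTILE = 0.95
THRESHOLD_SD_MULTIPLIER = 2.0


def _rates(regions: Sequence[RegionCount]) -> np.ndarray:
    counts = np.array([r.read_count for r in regions], dtype=float)
    lengths = np.array([r.length for r in regions], dtype=float)
    return counts / lengths


def gc_length_correct(
    regions: Sequence[RegionCount],
    gc_bin_width: float = GC_BIN_WIDTH,
    min_regions_per_bin: int = MIN_REGIONS_PER_GC_BIN,
) -> np.ndarray:
    """GC- and length-corrected coverage rates for one sample's regions.

    Returns one positive rate per region (in input order) wherever the input
    count is positive. All-zero input is an error.
    """
    rates = _rates(regions)
    if not np.any(rates > 0):
        raise ValueError("all region read counts are zero; nothing to correct")
    global_median = float(np.median(rates[rates > 0]))

    gc = np.array([r.gc_fraction for r in regions])
    bins = np.floor(gc / gc_bin_width).astype(int)
    corrected = np.empty_like(rates)
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() >= min_regions_per_bin:
            bin_median = float(np.median(rates[mask]))
            if bin_median <= 0:
                bin_median = global_median
        else:
            bin_median = global_median
        corrected[mask] = rates[mask] / bin_median * global_median
    return corrected


def _epsilon(lengths: Optional[np.ndarray]) -> np.ndarray | float:
    # half a read, expressed in rate units (reads per base)
    if lengths is None:
        return 1e-3
    return 0.5 / np.asarray(lengths, dtype=float)


def compute_log2_ratios(
    tumor_coverage: np.ndarray,
    panel_coverage: np.ndarray,
    lengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-region log2 of tumor coverage over the panel mean.

    ``panel_coverage`` is (n_panel, n_regions); the panel needs >= 2 members
    and an identical region grid.
    """
    tumor = np.asarray(tumor_coverage, dtype=float)
    panel = np.atleast_2d(np.asarray(panel_coverage, dtype=float))
    if panel.shape[0] < 2:
        raise ValueError("panel must contain at least 2 samples")
    if panel.shape[1] != tumor.shape[0]:
        raise ValueError(
            f"region grids differ: tumor has {tumor.shape[0]} regions, "
            f"panel has {panel.shape[1]}"
        )
    eps = _epsilon(lengths)
    return np.log2((tumor + eps) / (panel.mean(axis=0) + eps))


def panel_log2_ratios(
    panel_coverage: np.ndarray, lengths: Optional[np.ndarray] = None
) -> np.ndarray:
    """Leave-one-out log2 ratios for every panel member (n_panel, n_regions)."""
    panel = np.atleast_2d(np.asarray(panel_coverage, dtype=float))
    n = panel.shape[0]
    if n < 3:
        raise ValueError("leave-one-out panel ratios need at least 3 samples")
    eps = _epsilon(lengths)
    total = panel.sum(axis=0)
    loo_mean = (total[None, :] - panel) / (n - 1)
    return np.log2((panel + eps) / (loo_mean + eps))


def compute_z_scores(
    tumor_log2: np.ndarray,
    panel_log2: np.ndarray,
    global_threshold: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region z-scores of the tumor against the panel, plus thresholds.

    Returns ``(z, thresholds)``. The threshold is the 95th percentile of the
    panel's z-scores plus twice their SD — per region by default, pooled over
    all regions with ``global_threshold=True``.
    """
    tumor = np.asarray(tumor_log2, dtype=float)
    panel = np.atleast_2d(np.asarray(panel_log2, dtype=float))
    if panel.shape[0] < 2:
        raise ValueError("panel must contain at least 2 samples")

    mean = panel.mean(axis=0)
    sd = panel.std(axis=0, ddof=1)
    floored = sd < SD_FLOOR
    if np.any(floored):
        logger.warning(
            "%d region(s) have a near-constant panel (SD < %g); z-scores there "
            "are floored and may be extreme",
            int(floored.sum()),
            SD_FLOOR,
        )
    sd = np.maximum(sd, SD_FLOOR)
    z = (tumor - mean) / sd
    panel_z = (panel - mean[None, :]) / sd[None, :]

    if global_threshold:
        pooled = panel_z.ravel()
        thr = float(
            np.quantile(pooled, PANEL_QUANTILE, method="linear")
            + THRESHOLD_SD_MULTIPLIER * np.abs(pooled.std(ddof=1))
        )
        thresholds = np.full_like(z, thr)
    else:
        thresholds = np.quantile(
            panel_z, PANEL_QUANTILE, axis=0, method="linear"
        ) + THRESHOLD_SD_MULTIPLIER * np.abs(panel_z.std(axis=0, ddof=1))
    return z, thresholds


@dataclass
class CniResult:
    """Per-region z-scores, retention flags, and the summed CNI score."""

    sample_id: str
    z_scores: np.ndarray
    thresholds: np.ndarray
    retained: np.ndarray  # boolean
    cni: float


def cni_score(
    z_scores: np.ndarray,
    thresholds: np.ndarray,
    sample_id: str = "",
    two_sided: bool = False,
) -> CniResult:
    """Sum of z-scores strictly exceeding their retention threshold.

    One-sided by default (only amplifications contribute); with
    ``two_sided=True`` regions with |z| above threshold are retained and
    their |z| summed, letting deletions contribute.
    """
    z = np.asarray(z_scores, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    if two_sided:
        retained = np.abs(z) > thr
        total = float(np.abs(z)[retained].sum())
    else:
        retained = z > thr
        total = float(z[retained].sum())
    return CniResult(sample_id, z, thr, retained, total)


@dataclass
class CopyNumberProfile:
    """Per-region log2 ratios, CN estimates, gain/loss calls and burden."""

    sample_id: str
    log2_ratios: np.ndarray
    cn_estimates: np.ndarray
    calls: list[str]  # gain / loss / neutral
    n_gain: int
    n_loss: int
    burden: float


def call_cnv(
    cn_estimates: Optional[np.ndarray] = None,
    log2_ratios: Optional[np.ndarray] = None,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    sample_id: str = "",
) -> CopyNumberProfile:
    """Gain/loss/neutral calls from copy-number estimates.

    When absolute CN is not supplied it is derived from log2 ratios as
    CN = 2 * 2^log2. Strict inequalities: CN > gain_threshold is a gain,
    CN < loss_threshold a loss, boundary values neutral.
    """
    if cn_estimates is None:
        if log2_ratios is None:
            raise ValueError("provide cn_estimates or log2_ratios")
        log2_ratios = np.asarray(log2_ratios, dtype=float)
        cn_estimates = 2.0 * np.exp2(log2_ratios)
    else:
        cn_estimates = np.asarray(cn_estimates, dtype=float)
        if log2_ratios is None:
            log2_ratios = np.log2(np.maximum(cn_estimates, 1e-12) / 2.0)
    if np.any(cn_estimates < 0):
        raise ValueError("copy-number estimates must be non-negative")

    calls = [
        "gain" if cn > gain_threshold else "loss" if cn < loss_threshold else "neutral"
        for cn in cn_estimates
    ]
    n_gain = calls.count("gain")
    n_loss = calls.count("loss")
    burden = (n_gain + n_loss) / len(calls) if calls else 0.0
    return CopyNumberProfile(
        sample_id, np.asarray(log2_ratios), cn_estimates, calls, n_gain, n_loss, burden
    )


def analyze_sample(
    tumor_regions: Sequence[RegionCount],
    panel_regions: Mapping[str, Sequence[RegionCount]],
    two_sided: bool = False,
    global_threshold: bool = False,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> tuple[CopyNumberProfile, CniResult]:
    """Full per-sample pipeline: correction, log2 ratios, CNV calls, CNI score."""
    keys = [r.key for r in tumor_regions]
    for sid, regs in panel_regions.items():
        if [r.key for r in regs] != keys:
            raise ValueError(f"panel sample {sid} has a different region grid")
    lengths = np.array([r.length for r in tumor_regions], dtype=float)

    tumor_cov = gc_length_correct(tumor_regions)
    panel_cov = np.vstack([gc_length_correct(regs) for regs in panel_regions.values()])

    tumor_log2 = compute_log2_ratios(tumor_cov, panel_cov, lengths)
    panel_log2 = panel_log2_ratios(panel_cov, lengths)
    z, thresholds = compute_z_scores(tumor_log2, panel_log2, global_threshold)

    sample_id = tumor_regions[0].sample_id if tumor_regions else ""
    profile = call_cnv(
        log2_ratios=tumor_log2,
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
        sample_id=sample_id,
    )
    result = cni_score(z, thresholds, sample_id=sample_id, two_sided=two_sided)
    return profile, result
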