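"""Accessibility peak calling against a local Poisson background.

A documented stand-in for heavyweight peak callers: per-bin Poisson tests
against the maximum of flank-based local rates and the genome-wide mean,
BH-adjusted, with significant bins merged into peaks. Local rates exclude a
central hole so a genuine peak does not inflate its own background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bidir import CoverageTrack
from .regions import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_WINDOWS = (1000, 10000)
DEFAULT_MIN_LOG2FC = 1.0
DEFAULT_Q_MAX = 1e-5
LOCAL_EXCLUDE = 500  # bases removed from the middle of each local window
MERGE_GAP_BINS = 2


@dataclass(frozen=True)
class PeakCall:
    interval: GenomicInterval
    summit: int
    fold_change: float
    qvalue: float
    pvalue: float = 1.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")


def _local_means(counts: np.ndarray, window_bins: int, hole_bins: int) -> np.ndarray:
    """Mean count per bin in a centered window with the middle excluded."""
    ones = np.ones_like(counts, dtype=float)
    win_kernel = np.ones(max(window_bins, 1))
    win_sum = np.convolve(counts, win_kernel, mode="same")
    win_n = np.convolve(ones, win_kernel, mode="same")
    if hole_bins >= window_bins or hole_bins < 1:
        return win_sum / win_n
    hole_kernel = np.ones(hole_bins)
    hole_sum = np.convolve(counts, hole_kernel, mode="same")
    hole_n = np.convolve(ones, hole_kernel, mode="same")
    flank_n = np.maximum(win_n - hole_n, 1.0)
    return (win_sum - hole_sum) / flank_n


def call_peaks(
    track: CoverageTrack,
    lambda_windows: Sequence[int] = DEFAULT_LAMBDA_WINDOWS,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    q_max: float = DEFAULT_Q_MAX,
    local_exclude: int = LOCAL_EXCLUDE,
) -> list[PeakCall]:
    """Call enriched regions on an unstranded count track.

    Per-bin lambda is the maximum of flank-based local means (over
    ``lambda_windows``) and the track-wide mean. Bins with BH-adjusted
    Poisson q < q_max merge (gap <= 2 bins) into peaks; peaks whose summit
    fold change (log2 count/lambda) does not exceed ``min_log2fc`` are
    dropped. The track must hold raw counts, not normalized signal.
    """
    if not lambda_windows:
        raise ValueError("lambda_windows must be non-empty")
    if track.normalized:
        raise ValueError("call_peaks requires raw counts, not normalized signal")
    counts = track.total
    if counts.sum() == 0:
        return []
    bin_size = track.bin_size
    n_bins = len(counts)
    genome_mean = float(counts.mean())
    lam = np.full_like(counts, genome_mean, dtype=float)
    hole_bins = max(1, local_exclude // bin_size)
    for window in lambda_windows:
        wbins = max(1, int(window) // bin_size)
        lam = np.maximum(lam, _local_means(counts, wbins, hole_bins))
    lam = np.maximum(lam, 1e-9)

    # test peak-scale windowed sums rather than single bins: a centered
    # sliding sum over ~half the expected peak width against the matching
    # Poisson rate, which keeps usable power at low per-bin backgrounds
    test_bins = max(1, local_exclude // (2 * bin_size))
    kernel = np.ones(test_bins)
    window_sum = np.convolve(counts, kernel, mode="same")
    window_n = np.convolve(np.ones(n_bins), kernel, mode="same")
    pvalues = stats.poisson.sf(window_sum - 1, lam * window_n)
    _rej, qvalues, *_ = multipletests(pvalues, method="fdr_bh")
    significant = np.nonzero(qvalues < q_max)[0]
    if significant.size == 0:
        return []

    run_start = significant[0]
    prev = significant[0]
    runs: list[tuple[int, int]] = []
    for b in significant[1:]:
        if b - prev <= MERGE_GAP_BINS + 1:
            prev = b
            continue
        runs.append((run_start, prev))
        run_start = prev = b
    runs.append((run_start, prev))

    # refine each seed run to the contiguous bins clearly above background,
    # removing the slop of the test window and restoring full peak width
    extend_threshold = genome_mean * 2.0**min_log2fc
    pad = test_bins // 2 + 1
    refined: list[tuple[int, int]] = []
    for lo, hi in runs:
        lo = max(0, lo - pad)
        hi = min(n_bins - 1, hi + pad)
        above = np.nonzero(counts[lo : hi + 1] >= extend_threshold)[0]
        if above.size:
            lo, hi = lo + int(above[0]), lo + int(above[-1])
        while lo > 0 and counts[lo - 1] >= extend_threshold:
            lo -= 1
        while hi < n_bins - 1 and counts[hi + 1] >= extend_threshold:
            hi += 1
        if refined and lo <= refined[-1][1] + 1:
            refined[-1] = (refined[-1][0], max(hi, refined[-1][1]))
        else:
            refined.append((lo, hi))

    peaks: list[PeakCall] = []
    for lo, hi in refined:
        segment = counts[lo : hi + 1]
        summit_bin = lo + int(np.argmax(segment))
        summit = int((summit_bin + 0.5) * bin_size)
        fold = float(np.log2(max(counts[summit_bin], 1e-9) / lam[summit_bin]))
        if fold <= min_log2fc:
            continue
        start = lo * bin_size
        end = min((hi + 1) * bin_size, track.length)
        peaks.append(
            PeakCall(
                interval=GenomicInterval(track.chrom, start, end),
                summit=min(max(summit, start), end - 1),
                fold_change=fold,
                qvalue=float(qvalues[lo : hi + 1].min()),
                pvalue=float(pvalues[lo : hi + 1].min()),
            )
        )
    return peaks


def peak_presence(
    peak_sets: Mapping[str, Sequence[PeakCall]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Boolean presence of consensus peaks (union of all sets) per time point."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    all_intervals = [p.interval for calls in peak_sets.values() for p in calls]
    consensus = merge_intervals(all_intervals, gap=0)
    data = {}
    for timepoint, calls in peak_sets.items():
        intervals = [p.interval for p in calls]
        data[timepoint] = [
            any(peak.overlap_length(iv) >= min_overlap for iv in intervals)
            for peak in consensus
        ]
    return pd.DataFrame(data, index=[p.feature_id for p in consensus])


def reconcile_replicates(
    calls_a: Sequence[PeakCall],
    calls_b: Sequence[PeakCall],
    mode: str = "both",
    min_overlap: int = 1,
) -> list[PeakCall]:
    """Combine replicate peak calls.

    ``mode="both"`` keeps replicate-A peaks supported by >= min_overlap
    bases in replicate B; ``mode="either"`` returns the union.
    """
    if mode == "either":
        return list(calls_a) + [
            b
            for b in calls_b
            if not any(b.interval.overlap_length(a.interval) >= min_overlap for a in calls_a)
        ]
    if mode != "both":
        raise ValueError("mode must be 'both' or 'either'")
    return [
        a
        for a in calls_a
        if any(a.interval.overlap_length(b.interval) >= min_overlap for b in calls_b)
    ]


def write_narrowpeak(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """Export narrowPeak-style BED6+4 rows."""
    with open(path, "w") as handle:
        for i, p in enumerate(peaks):
            iv = p.interval
            score = int(min(1000, round(100 * p.fold_change)))
            neg_log_p = -np.log10(max(p.pvalue, 1e-300))
            neg_log_q = -np.log10(max(p.qvalue, 1e-300))
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i:05d}\t{score}\t.\t"
                f"{p.fold_change:.4f}\t{neg_log_p:.4f}\t{neg_log_q:.4f}\t"
                f"{p.summit - iv.start}\n"
            )
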