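"""Temporal classification of differential responses.

Transcript-level classes are decided from three pairwise contrasts
(30 min vs vehicle, 120 min vs vehicle, 120 min vs 30 min); accessibility
peaks are classified by presence/absence across time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .differential import DifferentialRecord
from .regions import GenomicInterval, merge_intervals

LABELS = ("early_peak", "early_plateau", "late", "unclassified")


@dataclass(frozen=True)
class ClusterThresholds:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class TemporalLabel:
    feature_id: str
    label: str
    evidence: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


class MissingContrastError(KeyError):
    """A feature lacks one of the three required contrasts."""


def _sig_up(record: DifferentialRecord, alpha: float) -> bool:
    return record.padj < alpha and record.log2fc > 0


def _sig_down(record: DifferentialRecord, alpha: float) -> bool:
    return record.padj < alpha and record.log2fc < 0


def classify_transcript_clusters(
    d30v0: Mapping[str, DifferentialRecord],
    d120v0: Mapping[str, DifferentialRecord],
    d120v30: Mapping[str, DifferentialRecord],
    thresholds: ClusterThresholds = ClusterThresholds(),
    mirrored: bool = False,
) -> list[TemporalLabel]:
    """Assign each feature exactly one temporal label.

    early_peak:     up(30v0) and down(120v30)
    early_plateau:  up(30v0) and up(120v0) and not down(120v30)
    late:           up(120v0) and up(120v30)
    with precedence early_peak > early_plateau > late; otherwise
    unclassified. ``mirrored=True`` swaps the roles of up and down to
    classify repression kinetics instead.
    """
    alpha = thresholds.alpha
    up, down = (_sig_down, _sig_up) if mirrored else (_sig_up, _sig_down)
    labels: list[TemporalLabel] = []
    for feature in d30v0:
        try:
            r30 = d30v0[feature]
            r120 = d120v0[feature]
            r120v30 = d120v30[feature]
        except KeyError as exc:
            raise MissingContrastError(
                f"feature {feature!r} is missing a contrast"
            ) from exc
        if up(r30, alpha) and down(r120v30, alpha):
            label = "early_peak"
        elif up(r30, alpha) and up(r120, alpha) and not down(r120v30, alpha):
            label = "early_plateau"
        elif up(r120, alpha) and up(r120v30, alpha):
            label = "late"
        else:
            label = "unclassified"
        labels.append(
            TemporalLabel(
                feature_id=feature,
                label=label,
                evidence=(
                    (r30.log2fc, r30.padj),
                    (r120.log2fc, r120.padj),
                    (r120v30.log2fc, r120v30.padj),
                ),
            )
        )
    return labels


def classify_peak_clusters(
    peaks_veh: Sequence[GenomicInterval],
    peaks_30: Sequence[GenomicInterval],
    peaks_120: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[TemporalLabel]:
    """Classify consensus accessibility peaks by presence/absence.

    A consensus peak (union of all three sets) is present at a time point
    when it overlaps any peak called there by >= min_overlap bases.
    early_peak = 30 only; early_plateau = 30 and 120, absent in vehicle;
    late = 120 only; anything else unclassified.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    consensus = merge_intervals(list(peaks_veh) + list(peaks_30) + list(peaks_120), gap=0)

    def present(peak: GenomicInterval, called: Sequence[GenomicInterval]) -> bool:
        return any(peak.overlap_length(c) >= min_overlap for c in called)

    labels: list[TemporalLabel] = []
    for peak in consensus:
        v = present(peak, peaks_veh)
        t30 = present(peak, peaks_30)
        t120 = present(peak, peaks_120)
        if not v and t30 and not t120:
            label = "early_peak"
        elif not v and t30 and t120:
            label = "early_plateau"
        elif not v and not t30 and t120:
            label = "late"
        else:
            label = "unclassified"
        labels.append(TemporalLabel(feature_id=peak.feature_id, label=label))
    return labels


def volcano_flags(
    records: Sequence[DifferentialRecord],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> dict[str, str]:
    """Flag records passing both the significance and fold-change gates."""
    if not 0 < alpha < 1 or lfc_min < 0:
        raise ValueError("invalid thresholds")
    return {
        r.feature_id: "both" if (r.padj < alpha and abs(r.log2fc) > lfc_min) else "other"
        for r in records
    }


def write_cluster_table(labels: Sequence[TemporalLabel], path: str | Path) -> None:
    header = (
        "# feature_id\tlabel\tlfc_30v0\tpadj_30v0\tlfc_120v0\tpadj_120v0"
        "\tlfc_120v30\tpadj_120v30\n"
    )
    with open(path, "w") as handle:
        handle.write(header)
        for lab in labels:
            if lab.evidence:
                ev = "\t".join(f"{x:.6g}" for pair in lab.evidence for x in pair)
            else:
                ev = "\t".join(["NA"] * 6)
            handle.write(f"{lab.feature_id}\t{lab.label}\t{ev}\n")
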