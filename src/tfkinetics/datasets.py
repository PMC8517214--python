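"""Bundled reference data.

``EARLY_PEAK_PANEL`` is a published panel of 21 rapidly induced, transient
response genes with their reported (log2 fold change, adjusted p) for the
30 min-vs-vehicle and 120 min-vs-30 min contrasts. Adjusted p-values
reported as 0 (below the publishing tool's resolution) are clamped to
1e-300 on conversion. The panel serves as a deterministic worked example
for the temporal classifier: every row satisfies the early-peak criteria.
"""

from __future__ import annotations

from .differential import DifferentialRecord

# gene, log2fc(30 vs vehicle), padj(30 vs vehicle),
#       log2fc(120 vs 30),     padj(120 vs 30)
EARLY_PEAK_PANEL: tuple[tuple[str, float, float, float, float], ...] = (
    ("IL24", 5.757, 0.0, -2.359, 6.81e-141),
    ("EGR1", 5.491, 0.0, -4.790, 0.0),
    ("KRT17", 5.128, 0.0, -2.467, 0.0),
    ("LHX4", 5.066, 0.0, -2.421, 3.72e-152),
    ("MAFF", 4.412, 0.0, -2.869, 0.0),
    ("TAGLN", 4.169, 0.0, -2.988, 0.0),
    ("CCN2", 3.798, 0.0, -3.018, 0.0),
    ("SPOCD1", 3.629, 0.0, -1.928, 1.75e-158),
    ("TIPARP", 2.777, 0.0, -1.975, 1.37e-282),
    ("SRF", 2.773, 0.0, -2.202, 5.42e-218),
    ("MYH9", 2.756, 0.0, -1.797, 6.60e-282),
    ("CYP1B1", 2.508, 0.0, -1.384, 9.16e-126),
    ("DNMT3L", 3.802, 8.63e-280, -2.116, 1.34e-116),
    ("AHRR", 1.794, 2.22e-238, -0.737, 4.55e-41),
    ("CYP1A1", 5.410, 1.51e-224, -1.466, 4.35e-45),
    ("ALDH3A1", 2.512, 2.58e-124, -0.992, 1.21e-22),
    ("ARNT2", 1.262, 5.65e-72, -0.590, 7.75e-17),
    ("MT2A", 1.318, 1.63e-64, -1.328, 1.34e-64),
    ("MEF2A", 0.836, 4.16e-35, -0.994, 6.95e-49),
    ("CCR7", 2.153, 1.43e-32, -1.560, 1.24e-18),
    ("CYP1A2", 4.662, 7.97e-11, -2.324, 9.82e-06),
)

P_CLAMP = 1e-300


def _record(gene: str, log2fc: float, padj: float) -> DifferentialRecord:
    padj = max(padj, P_CLAMP)
    return DifferentialRecord(
        feature_id=gene, log2fc=log2fc, pvalue=padj, padj=padj, mean_norm=0.0
    )


def early_peak_panel_contrasts() -> tuple[dict, dict, dict]:
    """The panel as (d30v0, d120v0, d120v30) record mappings.

    The 120-vs-vehicle contrast was not reported for the panel; a neutral
    record (log2fc 0, padj 1) is substituted — the early-peak criteria do
    not consult it.
    """
    d30v0 = {g: _record(g, lfc30, p30) for g, lfc30, p30, _l, _p in EARLY_PEAK_PANEL}
    d120v30 = {g: _record(g, lfc, p) for g, _l, _p, lfc, p in EARLY_PEAK_PANEL}
    d120v0 = {
        g: DifferentialRecord(
            feature_id=g, log2fc=0.0, pvalue=1.0, padj=1.0, mean_norm=0.0
        )
        for g, *_ in EARLY_PEAK_PANEL
    }
    return d30v0, d120v0, d120v30
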