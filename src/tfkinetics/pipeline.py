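"""End-to-end orchestration with fixed-name outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path
from typing import Mapping

from . import __version__
from .bidir import build_coverage, detect_bidirectionals, read_bedgraph, write_calls_bed
from .clusters import (
    ClusterThresholds,
    classify_peak_clusters,
    classify_transcript_clusters,
    volcano_flags,
    write_cluster_table,
)
from .config import PipelineConfig, stage_seed
from .differential import (
    nb_differential,
    rank_regions,
    write_differential_table,
)
from .motifscan import (
    enrichment_analysis,
    hits_around_centers,
    md_distribution,
    read_meme_motifs,
    score_threshold,
    write_enrichment_table,
    write_hits_table,
    write_md_matrix,
)
from .peaks import call_peaks, peak_presence, write_narrowpeak
from .regions import (
    consensus_rois,
    count_reads_in_regions,
    read_bed_reads,
    read_fasta,
    write_bed,
    write_count_matrix,
)
from .simulate import SimulationConfig, MotifEmbedding, simulate_all

logger = logging.getLogger(__name__)

CONTRASTS = (
    ("d30v0", "vehicle", "t30"),
    ("d120v0", "vehicle", "t120"),
    ("d120v30", "t30", "t120"),
)

STAGES = ("simulate", "detect", "counts", "diff", "cluster", "peaks", "scan", "enrich")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _condition_of(sample_id: str, overrides: Mapping[str, str]) -> str:
    if sample_id in overrides:
        return overrides[sample_id]
    return sample_id.rsplit("_rep", 1)[0]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest dictionary.

    Outputs are written with fixed names under ``outdir``. Any stage
    failure raises :class:`StageError` naming the stage; files written
    before the failure are left in place.
    """
    config.validate()
    config_hash = config.content_hash()  # before simulated paths are filled in
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def _register(path: Path) -> Path:
        outputs.append(path)
        return path

    # --- stage 0: simulate (optional) -------------------------------------
    paths = config.paths
    if config.simulate is not None:
        try:
            overrides = dict(config.simulate)
            embeddings = [
                MotifEmbedding(**e) if isinstance(e, dict) else e
                for e in overrides.pop("embeddings", [])
            ]
            sim_config = SimulationConfig(
                seed=stage_seed(config.seed, "simulate"),
                embeddings=embeddings,
                **overrides,
            )
            sim = simulate_all(sim_config, outdir / "inputs")
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", exc) from exc
        sim_paths = sim["paths"]
        paths.genome = sim_paths["genome"]
        paths.motifs = sim_paths["motifs"]
        paths.reads = sim_paths["reads"]
        paths.gene_counts = sim_paths["gene_counts"]
        paths.gene_samples = sim_paths["gene_samples"]
        paths.atac = sim_paths["atac"]
        paths.atac_bin_size = sim_config.atac_bin_size
        for sub in sorted(Path(outdir / "inputs").glob("*")):
            outputs.append(sub)

    # --- stage 1: detect ---------------------------------------------------
    try:
        genome = read_fasta(paths.genome)
        chrom_sizes = {chrom: len(seq) for chrom, seq in genome.items()}
        reads_by_sample = {
            sample: read_bed_reads(path, sample_id=sample)
            for sample, path in sorted(paths.reads.items())
        }
        per_sample_calls = []
        for sample, reads in reads_by_sample.items():
            tracks = build_coverage(
                reads,
                bin_size=config.detection.bin_size,
                library_size=max(len(reads), 1),
                chrom_sizes=chrom_sizes,
            )
            calls = []
            for track in tracks.values():
                calls.extend(
                    detect_bidirectionals(
                        track,
                        min_strength=config.detection.min_strength,
                        max_pair_distance=config.detection.max_pair_distance,
                        flank=config.detection.flank,
                    )
                )
            per_sample_calls.append((sample, [c.roi for c in calls]))
            write_calls_bed(calls, _register(outdir / f"bidir_calls_{sample}.bed"))
        rois = consensus_rois(per_sample_calls, gap=config.thresholds.merge_gap)
        # name consensus ROIs so downstream tables have stable ids
        from .regions import GenomicInterval, ROI

        rois = [
            ROI(
                GenomicInterval(
                    r.interval.chrom,
                    r.interval.start,
                    r.interval.end,
                    name=f"roi_{i:05d}",
                ),
                center=r.center,
                support=r.support,
            )
            for i, r in enumerate(rois)
        ]
        write_bed(
            [r.interval for r in rois], _register(outdir / "consensus_rois.bed")
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", exc) from exc

    # --- stage 2: counts ---------------------------------------------------
    try:
        conditions = {
            s: _condition_of(s, paths.read_conditions) for s in reads_by_sample
        }
        roi_counts = count_reads_in_regions(
            reads_by_sample,
            [r.interval for r in rois],
            sample_conditions=conditions,
            stranded=config.modes.stranded_counting,
        )
        write_count_matrix(
            roi_counts,
            _register(outdir / "roi_counts.tsv"),
            _register(outdir / "roi_samples.yaml"),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("counts", exc) from exc

    # --- stage 3: differential --------------------------------------------
    try:
        from .regions import read_count_matrix

        matrices = {"rois": roi_counts}
        if paths.gene_counts:
            matrices["genes"] = read_count_matrix(paths.gene_counts, paths.gene_samples)
        diff: dict[str, dict[str, list]] = {}
        ranked: dict[str, dict[str, object]] = {}
        for label, matrix in matrices.items():
            diff[label] = {}
            ranked[label] = {}
            for contrast, cond_a, cond_b in CONTRASTS:
                group_a = matrix.samples_for_condition(cond_a)
                group_b = matrix.samples_for_condition(cond_b)
                records = nb_differential(matrix, group_a, group_b)
                diff[label][contrast] = records
                ranked[label][contrast] = rank_regions(records)
                write_differential_table(
                    records, _register(outdir / f"diff_{label}_{contrast}.tsv")
                )
    except Exception as exc:  # noqa: BLE001
        raise StageError("diff", exc) from exc

    # --- stage 4: temporal clusters ---------------------------------------
    try:
        thresholds = ClusterThresholds(alpha=config.thresholds.alpha)
        for label in diff:
            by_feature = {
                contrast: {r.feature_id: r for r in diff[label][contrast]}
                for contrast, *_ in CONTRASTS
            }
            labels = classify_transcript_clusters(
                by_feature["d30v0"],
                by_feature["d120v0"],
                by_feature["d120v30"],
                thresholds=thresholds,
            )
            write_cluster_table(
                labels, _register(outdir / f"clusters_{label}.tsv")
            )
            flags = volcano_flags(
                diff[label]["d30v0"],
                alpha=config.thresholds.alpha,
                lfc_min=config.thresholds.lfc_min,
            )
            flag_path = _register(outdir / f"volcano_{label}_d30v0.tsv")
            with open(flag_path, "w") as handle:
                handle.write("# feature_id\tcategory\n")
                for fid, cat in flags.items():
                    handle.write(f"{fid}\t{cat}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", exc) from exc

    # --- stage 5: accessibility peaks -------------------------------------
    try:
        if paths.atac:
            peak_sets = {}
            for timepoint, bg_path in sorted(paths.atac.items()):
                tracks = read_bedgraph(
                    bg_path, bin_size=paths.atac_bin_size, chrom_sizes=chrom_sizes
                )
                calls = []
                for track in tracks.values():
                    calls.extend(
                        call_peaks(
                            track,
                            min_log2fc=config.thresholds.peak_min_log2fc,
                            q_max=config.thresholds.peak_q_max,
                        )
                    )
                peak_sets[timepoint] = calls
                write_narrowpeak(
                    calls, _register(outdir / f"atac_peaks_{timepoint}.narrowPeak")
                )
            presence = peak_presence(peak_sets, min_overlap=config.modes.min_overlap)
            presence_path = _register(outdir / "atac_presence.tsv")
            presence.to_csv(presence_path, sep="\t", index_label="# peak")
            peak_labels = classify_peak_clusters(
                [p.interval for p in peak_sets.get("vehicle", [])],
                [p.interval for p in peak_sets.get("t30", [])],
                [p.interval for p in peak_sets.get("t120", [])],
                min_overlap=config.modes.min_overlap,
            )
            write_cluster_table(
                peak_labels, _register(outdir / "clusters_atac_peaks.tsv")
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("peaks", exc) from exc

    # --- stage 6: motif scanning ------------------------------------------
    try:
        pwms = {p.motif_id: p for p in read_meme_motifs(paths.motifs)}
        hits_by_motif = {}
        distributions = []
        for motif_id, pwm in pwms.items():
            threshold = score_threshold(pwm, config.thresholds.motif_p_cutoff)
            hits = hits_around_centers(
                genome,
                rois,
                pwm,
                threshold,
                half_width=config.thresholds.scan_half_width,
            )
            hits_by_motif[motif_id] = hits
            distributions.append(
                md_distribution(
                    hits,
                    motif_id=motif_id,
                    half_width=config.thresholds.scan_half_width,
                )
            )
        all_hits = [h for hits in hits_by_motif.values() for h in hits]
        write_hits_table(all_hits, _register(outdir / "motif_hits.tsv"))
        write_md_matrix(distributions, _register(outdir / "md_matrix.tsv"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", exc) from exc

    # --- stage 7: enrichment ----------------------------------------------
    try:
        for contrast, *_ in CONTRASTS:
            results = enrichment_analysis(
                ranked["rois"][contrast],
                hits_by_motif,
                pwms,
                sigma=config.thresholds.sigma,
                mode=config.modes.pvalue_mode,
                n_perm=config.modes.n_perm,
                seed=stage_seed(config.seed, f"enrich.{contrast}"),
            )
            write_enrichment_table(
                results, _register(outdir / f"enrichment_rois_{contrast}.tsv")
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    # --- manifest ----------------------------------------------------------
    manifest = {
        "config_hash": config_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": list(STAGES),
        "thresholds": {
            f.name: getattr(config.thresholds, f.name)
            for f in fields(config.thresholds)
        },
        "files": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(set(outputs))
            if p.is_file()
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
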