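"""Synthetic inputs with ground truth for every pipeline stage.

Generates a random genome with motif words embedded near designated origin
centers, strand-paired nascent reads with exponential length decay around
those origins, NB-distributed gene counts following temporal archetypes,
and accessibility tracks with peaks that appear and disappear between time
points. One seed fixes every emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .bidir import CoverageTrack
from .regions import (
    CountMatrix,
    GenomicInterval,
    SampleInfo,
    StrandedRead,
    write_bed,
    write_count_matrix,
)
from .motifscan import PWM, write_meme_motifs

CHROM = "chr1"
CONDITIONS = ("vehicle", "t30", "t120")
ARCHETYPES = ("early_peak", "early_plateau", "late", "null")
READ_LENGTH = 30

# per-archetype log2 effect applied at each condition (scaled by the
# configured effect size)
_ARCHETYPE_PATTERN = {
    "early_peak": {"vehicle": 0.0, "t30": 1.0, "t120": 0.0},
    "early_plateau": {"vehicle": 0.0, "t30": 1.0, "t120": 1.0},
    "late": {"vehicle": 0.0, "t30": 0.0, "t120": 1.0},
    "null": {"vehicle": 0.0, "t30": 0.0, "t120": 0.0},
}


@dataclass
class MotifEmbedding:
    """How one motif is written into the genome around origin centers."""

    motif_id: str
    consensus: str
    displacement_sd: float = 150.0
    # probability of embedding at an origin, keyed by origin archetype;
    # 'default' applies to archetypes not listed
    probability: dict = field(default_factory=lambda: {"default": 0.0})

    def prob_for(self, archetype: str) -> float:
        return float(self.probability.get(archetype, self.probability.get("default", 0.0)))


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.5
    n_origins: int = 20
    decay_scale: float = 150.0
    reads_per_origin: int = 2000
    background_read_rate: float = 0.0  # background reads per base per sample
    archetype_effect: float = 2.0  # |log2fc| applied by non-null archetypes
    # null-dominated by default: median-of-ratios normalization assumes
    # most features are unchanged
    archetype_fractions: dict = field(
        default_factory=lambda: {
            "early_peak": 0.1,
            "early_plateau": 0.1,
            "late": 0.1,
            "null": 0.7,
        }
    )
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    n_genes: int = 300
    embeddings: list = field(default_factory=list)
    atac_bin_size: int = 50
    atac_background_mean: float = 2.0  # counts per bin
    atac_peak_fold: float = 8.0
    atac_peak_width: int = 500
    n_atac_peaks: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.decay_scale <= 0 or self.genome_length <= 0:
            raise ValueError("scales must be positive")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("archetype_fractions must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def default_motifs(pseudocount: float = 1e-3) -> list[PWM]:
    """A small built-in motif library (near point-mass PWMs)."""
    # widths >= 9 keep the default 1e-5 match cutoff attainable
    words = {
        "MOTIF_A": "ACGTGCGAT",
        "MOTIF_B": "TTGACTCAG",
        "MOTIF_C": "GGGACTTTCC",
        "MOTIF_D": "CCATATTAGG",
        "MOTIF_E": "GAGGTCAAGG",
        "MOTIF_F": "TGCATCATG",
        "MOTIF_G": "CACGCAATC",
        "MOTIF_H": "AGATAAGAC",
    }
    motifs = []
    for motif_id, word in words.items():
        w = len(word)
        matrix = np.full((w, 4), 0.01)
        for k, base in enumerate(word):
            matrix[k, "ACGT".index(base)] = 0.97
        motifs.append(PWM(motif_id=motif_id, matrix=matrix, pseudocount=pseudocount))
    return motifs


def plan_origins(config: SimulationConfig) -> list[dict]:
    """Place origins evenly (with jitter) and assign archetypes."""
    rng = config.rng(1)
    margin = 5000
    usable = config.genome_length - 2 * margin
    if usable <= 0 or config.n_origins < 1:
        raise ValueError("genome too short for the requested origins")
    spacing = usable / config.n_origins
    centers = [
        int(margin + (i + 0.5) * spacing + rng.integers(-spacing // 8, spacing // 8 + 1))
        for i in range(config.n_origins)
    ]
    labels: list[str] = []
    for archetype in ARCHETYPES:
        labels.extend(
            [archetype] * int(round(config.archetype_fractions.get(archetype, 0) * config.n_origins))
        )
    while len(labels) < config.n_origins:
        labels.append("null")
    labels = labels[: config.n_origins]
    return [
        {"origin_id": f"origin_{i:04d}", "center": c, "archetype": a}
        for i, (c, a) in enumerate(zip(centers, labels))
    ]


def generate_genome(
    config: SimulationConfig,
    origins: Sequence[Mapping] | None = None,
) -> tuple[dict[str, str], list[dict]]:
    """Random genome with motif words embedded around origin centers.

    Returns ({chrom: sequence}, embedding truth records). Each embedding
    record holds origin_id, motif_id, displacement, and position. Embedding
    displacements are Normal(0, sd) clipped to +/-1400; overlaps at one
    origin are re-sampled up to 100 times, then skipped with a warning.
    """
    rng = config.rng(2)
    if origins is None:
        origins = plan_origins(config)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.genome_length, p=probs)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()

    truth: list[dict] = []
    for origin in origins:
        occupied: list[tuple[int, int]] = []
        for emb in config.embeddings:
            if rng.random() >= emb.prob_for(origin["archetype"]):
                continue
            word = emb.consensus.encode("ascii")
            placed = False
            for _attempt in range(100):
                displacement = float(
                    np.clip(rng.normal(0.0, emb.displacement_sd), -1400, 1400)
                )
                start = int(origin["center"] + displacement - len(word) // 2)
                end = start + len(word)
                if start < 0 or end > config.genome_length:
                    continue
                if any(s < end and start < e for s, e in occupied):
                    continue
                seq[start:end] = np.frombuffer(word, dtype=np.uint8)
                occupied.append((start, end))
                truth.append(
                    {
                        "origin_id": origin["origin_id"],
                        "motif_id": emb.motif_id,
                        "position": start,
                        "displacement": (start + len(word) / 2.0) - origin["center"],
                    }
                )
                placed = True
                break
            if not placed:
                import warnings

                warnings.warn(
                    f"could not place {emb.motif_id} at {origin['origin_id']}",
                    stacklevel=2,
                )
    return {CHROM: seq.tobytes().decode("ascii")}, truth


def _condition_strength(archetype: str, condition: str, effect: float) -> float:
    return float(2.0 ** (_ARCHETYPE_PATTERN[archetype][condition] * effect))


def simulate_nascent_reads(
    config: SimulationConfig,
    origins: Sequence[Mapping] | None = None,
) -> tuple[dict[str, list[StrandedRead]], list[dict]]:
    """Strand-paired reads with exponential 5'-end decay around origins.

    Per origin and condition, the read count is Poisson with mean
    strength x reads_per_origin; strands are assigned with probability 1/2;
    plus-strand 5' ends fall at center + Exp(decay_scale) and minus-strand
    at center - Exp(decay_scale). Uniform background reads are added at the
    configured per-base rate. Returns (reads per sample, origin truth).
    """
    if origins is None:
        origins = plan_origins(config)
    rng = config.rng(3)
    samples: dict[str, list[StrandedRead]] = {}
    truth: list[dict] = []
    for origin in origins:
        record = dict(origin)
        record["strength"] = {
            c: _condition_strength(origin["archetype"], c, config.archetype_effect)
            for c in CONDITIONS
        }
        truth.append(record)
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{condition}_rep{rep}"
            reads: list[StrandedRead] = []
            for origin in truth:
                strength = origin["strength"][condition]
                n = rng.poisson(strength * config.reads_per_origin)
                if n == 0:
                    continue
                strands = rng.random(n) < 0.5
                offsets = rng.exponential(config.decay_scale, size=n).astype(np.int64)
                center = origin["center"]
                for plus, off in zip(strands, offsets):
                    if plus:
                        p5 = center + int(off)
                        start, end, strand = p5, p5 + READ_LENGTH, "+"
                    else:
                        p5 = center - int(off)
                        start, end, strand = p5 - READ_LENGTH + 1, p5 + 1, "-"
                    start = max(0, start)
                    end = min(config.genome_length, end)
                    if end <= start:
                        continue
                    reads.append(
                        StrandedRead(
                            GenomicInterval(CHROM, start, end, strand=strand),
                            sample_id=sample_id,
                        )
                    )
            n_bg = rng.poisson(config.background_read_rate * config.genome_length)
            if n_bg:
                starts = rng.integers(0, config.genome_length - READ_LENGTH, size=n_bg)
                bg_strands = rng.random(n_bg) < 0.5
                for s, plus in zip(starts, bg_strands):
                    reads.append(
                        StrandedRead(
                            GenomicInterval(
                                CHROM, int(s), int(s) + READ_LENGTH,
                                strand="+" if plus else "-",
                            ),
                            sample_id=sample_id,
                        )
                    )
            reads.sort(key=lambda r: (r.interval.start, r.interval.strand))
            samples[sample_id] = reads
    return samples, truth


def simulate_gene_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, list[dict]]:
    """NB gene counts across three conditions following temporal archetypes."""
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = config.rng(4)
    archetypes: list[str] = []
    for archetype in ARCHETYPES:
        archetypes.extend(
            [archetype]
            * int(round(config.archetype_fractions.get(archetype, 0) * config.n_genes))
        )
    while len(archetypes) < config.n_genes:
        archetypes.append("null")
    archetypes = archetypes[: config.n_genes]

    baselines = np.exp(
        rng.uniform(np.log(50.0), np.log(5000.0), size=config.n_genes)
    )
    samples = [
        SampleInfo(sample_id=f"{c}_rep{r}", condition=c, replicate=r)
        for c in CONDITIONS
        for r in range(1, config.n_replicates + 1)
    ]
    counts = np.zeros((config.n_genes, len(samples)), dtype=np.int64)
    r_param = 1.0 / config.nb_dispersion
    truth: list[dict] = []
    for i, (archetype, base) in enumerate(zip(archetypes, baselines)):
        for j, sample in enumerate(samples):
            mu = base * _condition_strength(
                archetype, sample.condition, config.archetype_effect
            )
            p = r_param / (r_param + mu)
            counts[i, j] = rng.negative_binomial(r_param, p)
        truth.append(
            {"gene_id": f"gene_{i:05d}", "archetype": archetype, "baseline": float(base)}
        )
    features = [t["gene_id"] for t in truth]
    return CountMatrix(features=features, samples=samples, counts=counts), truth


def plan_atac_schedule(config: SimulationConfig) -> list[dict]:
    """Assign each simulated accessibility peak a time-point subset."""
    rng = config.rng(5)
    margin = 2000
    usable = config.genome_length - 2 * margin
    spacing = usable / max(config.n_atac_peaks, 1)
    schedules = (
        ("t30",),
        ("t30", "t120"),
        ("t120",),
        ("vehicle", "t30", "t120"),
    )
    plan: list[dict] = []
    for i in range(config.n_atac_peaks):
        start = int(margin + (i + 0.5) * spacing - config.atac_peak_width // 2)
        start += int(rng.integers(-spacing // 8, spacing // 8 + 1))
        plan.append(
            {
                "peak_id": f"atacpeak_{i:04d}",
                "start": start,
                "end": start + config.atac_peak_width,
                "present_at": list(schedules[i % len(schedules)]),
            }
        )
    return plan


def simulate_atac(
    config: SimulationConfig,
    schedule: Sequence[Mapping] | None = None,
) -> tuple[dict[str, CoverageTrack], list[dict]]:
    """Poisson background tracks plus flat-top peaks per scheduled time point."""
    if schedule is None:
        schedule = plan_atac_schedule(config)
    rng = config.rng(6)
    bin_size = config.atac_bin_size
    n_bins = -(-config.genome_length // bin_size)
    tracks: dict[str, CoverageTrack] = {}
    for timepoint in CONDITIONS:
        lam = np.full(n_bins, config.atac_background_mean)
        for peak in schedule:
            if timepoint in peak["present_at"]:
                lo = peak["start"] // bin_size
                hi = -(-peak["end"] // bin_size)
                lam[lo:hi] = config.atac_background_mean * config.atac_peak_fold
        values = rng.poisson(lam).astype(float)
        tracks[timepoint] = CoverageTrack.unstranded(CHROM, bin_size, values)
    return tracks, [dict(p) for p in schedule]


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for chrom, seq in genome.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_track_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    values = track.total
    with open(path, "w") as handle:
        for i, v in enumerate(values):
            if v != 0:
                start = i * track.bin_size
                handle.write(
                    f"{track.chrom}\t{start}\t{start + track.bin_size}\t{v:g}\n"
                )


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input; returns paths and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.embeddings:
        config.embeddings = default_embeddings()
    origins = plan_origins(config)
    genome, embedding_truth = generate_genome(config, origins)
    reads, origin_truth = simulate_nascent_reads(config, origins)
    gene_counts, gene_truth = simulate_gene_counts(config)
    atac_tracks, atac_truth = simulate_atac(config)
    motifs = default_motifs()

    paths: dict[str, str] = {}
    fasta = outdir / "genome.fa"
    write_fasta(genome, fasta)
    paths["genome"] = str(fasta)

    meme = outdir / "motifs.meme"
    write_meme_motifs(motifs, meme)
    paths["motifs"] = str(meme)

    read_paths: dict[str, str] = {}
    for sample_id, sample_reads in reads.items():
        bed = outdir / f"reads_{sample_id}.bed"
        write_bed([r.interval for r in sample_reads], bed)
        read_paths[sample_id] = str(bed)
    paths["reads"] = read_paths

    counts_path = outdir / "gene_counts.tsv"
    samples_path = outdir / "gene_samples.yaml"
    write_count_matrix(gene_counts, counts_path, samples_path)
    paths["gene_counts"] = str(counts_path)
    paths["gene_samples"] = str(samples_path)

    atac_paths: dict[str, str] = {}
    for timepoint, track in atac_tracks.items():
        bg = outdir / f"atac_{timepoint}.bedgraph"
        write_track_bedgraph(track, bg)
        atac_paths[timepoint] = str(bg)
    paths["atac"] = atac_paths

    truth = {
        "origins": origin_truth,
        "embeddings": embedding_truth,
        "genes": gene_truth,
        "atac_peaks": atac_truth,
        "config": _config_to_dict(config),
    }
    truth_path = outdir / "truth.yaml"
    with open(truth_path, "w") as handle:
        yaml.safe_dump(truth, handle, sort_keys=True)
    paths["truth"] = str(truth_path)
    return {"paths": paths, "truth": truth}


def default_embeddings() -> list[MotifEmbedding]:
    """Embedding plan: one motif tracks early_peak origins, one is uniform."""
    return [
        MotifEmbedding(
            motif_id="MOTIF_A",
            consensus="ACGTGCGAT",
            displacement_sd=150.0,
            probability={"early_peak": 0.9, "default": 0.1},
        ),
        MotifEmbedding(
            motif_id="MOTIF_B",
            consensus="TTGACTCAG",
            displacement_sd=150.0,
            probability={"default": 0.3},
        ),
    ]


def _config_to_dict(config: SimulationConfig) -> dict:
    data = asdict(config)
    data["embeddings"] = [asdict(e) if not isinstance(e, dict) else e for e in config.embeddings]
    return data
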