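"""PWM handling, exact score-distribution thresholds, sequence scanning,
motif-displacement profiling, and rank-based enrichment scoring.

Scanning reimplements plain log-odds scoring against an order-0 background
with thresholds derived from the exact dynamic-programming convolution of
the per-position score distribution (discretized at 1e-3 bits). The
enrichment statistic is a rank-weighted score with exponential displacement
weighting; it is validated by calibration and recovery simulations.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import RankedTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_IDX = np.array([3, 2, 1, 0])
DEFAULT_PSEUDOCOUNT = 1e-3
SCORE_STEP_BITS = 1e-3
DEFAULT_HALF_WIDTH = 1500
DEFAULT_SIGMA = 150.0


class MemeParseError(ValueError):
    """Raised for malformed MEME minimal-format motif files."""


@dataclass
class PWM:
    """Position probability matrix with log-odds scoring support."""

    motif_id: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be width x 4")
        if self.pseudocount > 0:
            self.matrix = (self.matrix + self.pseudocount) / (
                1.0 + 4.0 * self.pseudocount
            )
        row_sums = self.matrix.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-4):
            raise ValueError("matrix rows must sum to 1")
        self.matrix = self.matrix / row_sums[:, None]
        if np.any(self.matrix <= 0):
            raise ValueError("matrix entries must be positive after pseudocount")
        if abs(self.background.sum() - 1.0) > 1e-6 or np.any(self.background <= 0):
            raise ValueError("background must be a positive distribution over ACGT")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def gc_fraction(self) -> float:
        return float(self.matrix[:, [1, 2]].sum(axis=1).mean())

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background), in bits."""
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement_log_odds(self) -> np.ndarray:
        return self.log_odds[::-1, ::-1]


@dataclass(frozen=True)
class MotifHit:
    roi_id: str
    motif_id: str
    position: int  # forward-strand window start, genome coordinates
    strand: str
    score: float
    displacement: float  # hit midpoint minus ROI center
    best: bool = False


@dataclass
class MDDistribution:
    """Normalized histogram of motif-hit displacements around ROI centers."""

    motif_id: str
    bin_edges: np.ndarray
    fractions: np.ndarray
    n_hits: int

    @property
    def has_hits(self) -> bool:
        return self.n_hits > 0


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    e_raw: float
    e_corrected: float
    z: float
    pvalue: float
    padj: float
    n_hit_rois: int


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme_motifs(
    path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[PWM]:
    """Parse a MEME minimal-format motif file.

    Background frequencies come from the header when present, otherwise a
    uniform 0.25 default. Probability rows that do not sum to ~1 raise
    :class:`MemeParseError`.
    """
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    with open(path) as handle:
        lines = handle.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freqs = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freqs.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MemeParseError(f"motif {motif_id}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise MemeParseError(f"motif {motif_id}: missing probability matrix")
            header = lines[i].strip()
            match = re.search(r"\bw\s*=\s*(\d+)", header)
            width = int(match.group(1)) if match else None
            rows: list[list[float]] = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                values = [float(v) for v in stripped.split()]
                if len(values) != 4:
                    raise MemeParseError(
                        f"motif {motif_id}: expected 4 probabilities per row"
                    )
                if abs(sum(values) - 1.0) > 1e-3:
                    raise MemeParseError(
                        f"motif {motif_id}: probability row does not sum to 1"
                    )
                rows.append(values)
                i += 1
            if width is not None and len(rows) != width:
                raise MemeParseError(
                    f"motif {motif_id}: expected {width} rows, got {len(rows)}"
                )
            if not rows:
                raise MemeParseError(f"motif {motif_id}: empty probability matrix")
            motifs.append(
                PWM(
                    motif_id=motif_id,
                    matrix=np.array(rows),
                    background=background,
                    pseudocount=pseudocount,
                )
            )
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        handle.write("strands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            handle.write("Background letter frequencies\n")
            handle.write(
                " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n"
            )
        for pwm in motifs:
            handle.write(f"MOTIF {pwm.motif_id}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            handle.write("\n")


# ---------------------------------------------------------------------------
# Exact score distribution and thresholds
# ---------------------------------------------------------------------------

def score_distribution(
    pwm: PWM, step: float = SCORE_STEP_BITS
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score under the background model.

    Per-position scores are discretized to multiples of ``step`` bits and
    convolved by dynamic programming. Returns (scores, probabilities) for
    all attainable discretized totals with probability > 0.
    """
    grid = np.rint(pwm.log_odds / step).astype(np.int64)  # width x 4
    lo = int(grid.min(axis=1).sum())
    hi = int(grid.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    offsets = grid - grid.min(axis=1)[:, None]
    dist[0] = 1.0
    cur_len = 1
    for k in range(pwm.width):
        span = int(offsets[k].max())
        new = np.zeros(cur_len + span)
        for b in range(4):
            new[offsets[k, b] : offsets[k, b] + cur_len] += (
                dist[:cur_len] * pwm.background[b]
            )
        cur_len += span
        dist[: cur_len] = new
        if cur_len < len(dist):
            dist[cur_len:] = 0.0
    probs = dist[:cur_len]
    scores = (lo + np.arange(cur_len)) * step
    mask = probs > 0
    return scores[mask], probs[mask]


def score_threshold(
    pwm: PWM, p_cutoff: float, step: float = SCORE_STEP_BITS
) -> float:
    """Smallest threshold t with P(score >= t | background) <= p_cutoff.

    When even the best word exceeds the cutoff probability, the maximum
    attainable score is returned with a warning.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must lie in (0, 1]")
    scores, probs = score_distribution(pwm, step=step)
    tail = np.cumsum(probs[::-1])[::-1]
    # grid values can round up to half a step per position above the exact
    # log-odds total; subtract that slack so exact-score scanning admits
    # every word the discretized threshold intends to admit
    slack = 0.5 * step * pwm.width
    passing = np.nonzero(tail <= p_cutoff)[0]
    if passing.size == 0:
        warnings.warn(
            f"motif {pwm.motif_id}: p_cutoff {p_cutoff} below the probability "
            "of the single best word; using the maximum score",
            stacklevel=2,
        )
        return float(scores[-1]) - slack
    return float(scores[passing[0]]) - slack


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def encode_sequence(sequence: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def scan_sequence(
    pwm: PWM, sequence: str, threshold: float
) -> list[tuple[int, str, float]]:
    """Report every window scoring >= threshold on either strand.

    Positions are 0-based forward-strand window starts. Windows containing
    an ambiguous base (N) are skipped entirely.
    """
    w = pwm.width
    codes = encode_sequence(sequence)
    n = len(codes) - w + 1
    if n <= 0:
        return []
    lod = pwm.log_odds
    lod_rc = pwm.reverse_complement_log_odds()
    fwd = np.zeros(n)
    rev = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for k in range(w):
        window_codes = codes[k : k + n]
        bad = window_codes < 0
        valid &= ~bad
        safe = np.where(bad, 0, window_codes)
        fwd += lod[k, safe]
        rev += lod_rc[k, safe]
    hits: list[tuple[int, str, float]] = []
    for pos in np.nonzero(valid & (fwd >= threshold))[0]:
        hits.append((int(pos), "+", float(fwd[pos])))
    for pos in np.nonzero(valid & (rev >= threshold))[0]:
        hits.append((int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract [start, end) from a dict of strings or a pyfaidx.Fasta."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from genome")
    record = genome[chrom]
    if isinstance(record, str):
        return record[start:end]
    fragment = record[start:end]
    return fragment if isinstance(fragment, str) else str(fragment)


def _chrom_length(genome, chrom: str) -> int:
    record = genome[chrom]
    return len(record)


def hits_around_centers(
    genome,
    rois: Sequence,
    pwm: PWM,
    threshold: float,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[MotifHit]:
    """Scan center +/- half_width windows of each ROI for motif hits.

    Windows are clipped at chromosome edges. Displacement is the hit
    midpoint minus the ROI center. Per ROI the best hit (max score; ties by
    smallest |displacement|) is flagged ``best=True``; all hits are
    returned for displacement profiling.
    """
    hits: list[MotifHit] = []
    for roi in rois:
        chrom = roi.interval.chrom
        center = roi.center
        length = _chrom_length(genome, chrom)
        start = max(0, center - half_width)
        end = min(length, center + half_width)
        sequence = _fetch_sequence(genome, chrom, start, end)
        raw = scan_sequence(pwm, sequence, threshold)
        roi_hits = [
            MotifHit(
                roi_id=roi.roi_id,
                motif_id=pwm.motif_id,
                position=start + pos,
                strand=strand,
                score=score,
                displacement=(start + pos + pwm.width / 2.0) - center,
            )
            for pos, strand, score in raw
        ]
        if roi_hits:
            best = min(roi_hits, key=lambda h: (-h.score, abs(h.displacement)))
            roi_hits = [
                MotifHit(
                    roi_id=h.roi_id,
                    motif_id=h.motif_id,
                    position=h.position,
                    strand=h.strand,
                    score=h.score,
                    displacement=h.displacement,
                    best=h is best,
                )
                for h in roi_hits
            ]
        hits.extend(roi_hits)
    return hits


def best_hits_by_roi(hits: Iterable[MotifHit]) -> dict[str, MotifHit]:
    return {h.roi_id: h for h in hits if h.best}


# ---------------------------------------------------------------------------
# Displacement distributions and enrichment
# ---------------------------------------------------------------------------

def md_distribution(
    hits: Sequence[MotifHit],
    motif_id: str = "",
    n_bins: int = 100,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> MDDistribution:
    """Histogram of hit displacements over [-half_width, half_width].

    Fractions sum to 1 when any hit exists; a hitless motif yields all-zero
    fractions flagged via ``has_hits``.
    """
    if n_bins < 2 or n_bins % 2 != 0:
        raise ValueError("n_bins must be an even number >= 2")
    edges = np.linspace(-half_width, half_width, n_bins + 1)
    if not motif_id and hits:
        motif_id = hits[0].motif_id
    displacements = np.array([h.displacement for h in hits], dtype=float)
    if displacements.size == 0:
        return MDDistribution(motif_id, edges, np.zeros(n_bins), n_hits=0)
    counts, _ = np.histogram(np.clip(displacements, -half_width, half_width), bins=edges)
    fractions = counts / counts.sum()
    return MDDistribution(motif_id, edges, fractions, n_hits=int(displacements.size))


def enrichment_score(
    ranked: RankedTable | Sequence[str],
    best_hits: Mapping[str, MotifHit | float],
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Rank-weighted enrichment of motif-bearing ROIs near the top.

    With normalized ranks r_i = (i - 0.5)/N, the score is
    sum(w_i * (1 - 2 r_i)) / sum(w_i) over hit-bearing ROIs, where
    w_i = exp(-|displacement_i| / sigma). Bounded in [-1, 1]; 0 when no
    ROI carries a hit.
    """
    feature_ids = ranked.feature_ids if isinstance(ranked, RankedTable) else list(ranked)
    n = len(feature_ids)
    if n < 10:
        raise ValueError("enrichment requires >= 10 ranked ROIs")
    num = 0.0
    den = 0.0
    for i, roi_id in enumerate(feature_ids):
        hit = best_hits.get(roi_id)
        if hit is None:
            continue
        displacement = hit.displacement if isinstance(hit, MotifHit) else float(hit)
        weight = float(np.exp(-abs(displacement) / sigma))
        r = (i + 0.5) / n
        num += weight * (1.0 - 2.0 * r)
        den += weight
    if den == 0.0:
        return 0.0
    return num / den


def gc_correct(
    results: Sequence[tuple[str, float, float]]
) -> dict[str, float]:
    """Residualize enrichment scores on motif GC content by OLS.

    Input is (motif_id, e_raw, gc_fraction) per motif. With fewer than five
    motifs no correction is applied (warning). When GC variance is
    degenerate the correction reduces to mean-centering.
    """
    if len(results) < 5:
        warnings.warn("fewer than 5 motifs; skipping GC correction", stacklevel=2)
        return {motif_id: e for motif_id, e, _gc in results}
    e = np.array([r[1] for r in results])
    gc = np.array([r[2] for r in results])
    if np.var(gc) < 1e-6:
        fitted = np.full_like(e, e.mean())
    else:
        design = np.column_stack([np.ones_like(gc), gc])
        coef, *_ = np.linalg.lstsq(design, e, rcond=None)
        fitted = design @ coef
    return {r[0]: float(e_i - f_i) for r, e_i, f_i in zip(results, e, fitted)}


def motif_pvalues(
    e_corrected: Mapping[str, float],
    ranked: RankedTable | Sequence[str] | None = None,
    best_hits_by_motif: Mapping[str, Mapping[str, MotifHit | float]] | None = None,
    mode: str = "z",
    n_perm: int = 1000,
    seed: int = 0,
    sigma: float = DEFAULT_SIGMA,
) -> dict[str, tuple[float, float, float]]:
    """Per-motif (z, pvalue, padj).

    ``mode="z"``: standardize corrected scores across the motif set and use
    a two-sided normal p-value. ``mode="permutation"``: shuffle ROI ranks
    ``n_perm`` times with the given seed, recompute the raw enrichment
    score, and report the two-sided empirical p with +1 smoothing (the raw,
    uncorrected score is permuted because GC correction is a cross-motif
    adjustment). BH adjustment is applied across motifs in both modes.
    """
    motif_ids = list(e_corrected.keys())
    if mode == "z":
        values = np.array([e_corrected[m] for m in motif_ids])
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        if sd == 0:
            raise ValueError(
                "zero variance across motifs; Z mode unavailable, use permutation mode"
            )
        z = (values - values.mean()) / sd
        pvalues = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    elif mode == "permutation":
        if ranked is None or best_hits_by_motif is None:
            raise ValueError("permutation mode needs ranked ROIs and per-motif hits")
        if n_perm < 100:
            raise ValueError("permutation mode requires n_perm >= 100")
        feature_ids = (
            ranked.feature_ids if isinstance(ranked, RankedTable) else list(ranked)
        )
        n = len(feature_ids)
        index = {fid: i for i, fid in enumerate(feature_ids)}
        u = 1.0 - 2.0 * (np.arange(n) + 0.5) / n
        rng = np.random.default_rng(seed)
        # per motif: indices of hit ROIs and weights
        motif_hits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        observed: dict[str, float] = {}
        for motif_id in motif_ids:
            hits = best_hits_by_motif.get(motif_id, {})
            idx = []
            weights = []
            for roi_id, hit in hits.items():
                if roi_id not in index:
                    continue
                displacement = (
                    hit.displacement if isinstance(hit, MotifHit) else float(hit)
                )
                idx.append(index[roi_id])
                weights.append(np.exp(-abs(displacement) / sigma))
            idx_arr = np.array(idx, dtype=np.int64)
            w_arr = np.array(weights)
            motif_hits[motif_id] = (idx_arr, w_arr)
            observed[motif_id] = (
                float((w_arr * u[idx_arr]).sum() / w_arr.sum()) if w_arr.size else 0.0
            )
        exceed = {m: 0 for m in motif_ids}
        for _ in range(n_perm):
            perm_u = rng.permutation(u)
            for motif_id in motif_ids:
                idx_arr, w_arr = motif_hits[motif_id]
                if w_arr.size == 0:
                    exceed[motif_id] += 1
                    continue
                e_perm = float((w_arr * perm_u[idx_arr]).sum() / w_arr.sum())
                if abs(e_perm) >= abs(observed[motif_id]) - 1e-15:
                    exceed[motif_id] += 1
        pvalues = np.array(
            [(1.0 + exceed[m]) / (n_perm + 1.0) for m in motif_ids]
        )
        values = np.array([observed[m] for m in motif_ids])
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _rej, padj, *_ = multipletests(pvalues, method="fdr_bh")
    padj = np.maximum(padj, pvalues)
    return {
        m: (float(z_i), float(p_i), float(q_i))
        for m, z_i, p_i, q_i in zip(motif_ids, z, pvalues, padj)
    }


def enrichment_analysis(
    ranked: RankedTable,
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    pwms: Mapping[str, PWM],
    sigma: float = DEFAULT_SIGMA,
    mode: str = "z",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Compose best-hit extraction, raw scores, GC correction, and p-values."""
    best: dict[str, dict[str, MotifHit]] = {}
    e_raw: dict[str, float] = {}
    for motif_id, hits in hits_by_motif.items():
        best[motif_id] = best_hits_by_roi(hits)
        e_raw[motif_id] = enrichment_score(ranked, best[motif_id], sigma=sigma)
    triples = [
        (motif_id, e_raw[motif_id], pwms[motif_id].gc_fraction)
        for motif_id in hits_by_motif
    ]
    e_corrected = gc_correct(triples)
    pvals = motif_pvalues(
        e_corrected,
        ranked=ranked,
        best_hits_by_motif=best,
        mode=mode,
        n_perm=n_perm,
        seed=seed,
        sigma=sigma,
    )
    return [
        EnrichmentResult(
            motif_id=motif_id,
            e_raw=e_raw[motif_id],
            e_corrected=e_corrected[motif_id],
            z=pvals[motif_id][0],
            pvalue=pvals[motif_id][1],
            padj=pvals[motif_id][2],
            n_hit_rois=len(best[motif_id]),
        )
        for motif_id in hits_by_motif
    ]


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def write_hits_table(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("# roi_id\tmotif_id\tposition\tstrand\tscore\tdisplacement\tbest\n")
        for h in hits:
            handle.write(
                f"{h.roi_id}\t{h.motif_id}\t{h.position}\t{h.strand}\t"
                f"{h.score:.4f}\t{h.displacement:g}\t{int(h.best)}\n"
            )


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("# motif_id\te_raw\te_corrected\tz\tpvalue\tpadj\tn_hit_rois\n")
        for r in results:
            handle.write(
                f"{r.motif_id}\t{r.e_raw:.6g}\t{r.e_corrected:.6g}\t{r.z:.6g}\t"
                f"{r.pvalue:.6g}\t{r.padj:.6g}\t{r.n_hit_rois}\n"
            )


def write_md_matrix(
    distributions: Sequence[MDDistribution], path: str | Path
) -> None:
    """Export bin x motif fractions as TSV."""
    with open(path, "w") as handle:
        handle.write(
            "# bin_start\tbin_end\t" + "\t".join(d.motif_id for d in distributions) + "\n"
        )
        if not distributions:
            return
        edges = distributions[0].bin_edges
        for i in range(len(edges) - 1):
            row = "\t".join(f"{d.fractions[i]:.6g}" for d in distributions)
            handle.write(f"{edges[i]:g}\t{edges[i + 1]:g}\t{row}\n")
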