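import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfkinetics.motifscan import (
    MemeParseError,
    MotifHit,
    PWM,
    enrichment_score,
    gc_correct,
    hits_around_centers,
    md_distribution,
    motif_pvalues,
    read_meme_motifs,
    scan_sequence,
    score_distribution,
    score_threshold,
    write_meme_motifs,
)
from tfkinetics.regions import GenomicInterval, ROI

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def random_pwm(rng, width=None, motif_id="m", background=None):
    width = width or int(rng.integers(3, 9))
    matrix = rng.dirichlet(np.ones(4) * 0.5, size=width)
    bg = background if background is not None else np.full(4, 0.25)
    return PWM(motif_id, matrix, background=bg)


def point_mass_pwm(word, motif_id="pm", pseudocount=1e-9):
    matrix = np.zeros((len(word), 4))
    for k, base in enumerate(word):
        matrix[k, "ACGT".index(base)] = 1.0
    return PWM(motif_id, matrix, pseudocount=pseudocount)


def brute_force_scan(pwm, seq, threshold):
    lod = pwm.log_odds
    w = pwm.width
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if "N" in window:
            continue
        fwd = sum(lod[k, "ACGT".index(window[k])] for k in range(w))
        rc = "".join(COMPLEMENT[c] for c in reversed(window))
        rev = sum(lod[k, "ACGT".index(rc[k])] for k in range(w))
        if fwd >= threshold:
            hits.append((i, "+", fwd))
        if rev >= threshold:
            hits.append((i, "-", rev))
    return sorted(hits, key=lambda h: (h[0], h[1]))


class TestPWM:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM("x", np.array([[0.9, 0.0, 0.0, 0.0]]), pseudocount=0.0)

    def test_gc_fraction_bounds(self, rng):
        for _ in range(10):
            pwm = random_pwm(rng)
            assert 0.0 <= pwm.gc_fraction <= 1.0

    def test_consensus(self):
        pwm = point_mass_pwm("ACGG")
        assert pwm.consensus == "ACGG"


class TestMemeIO:
    def test_single_motif(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF TEST1\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0\n"
            "0.97 0.01 0.01 0.01\n0.01 0.97 0.01 0.01\n"
            "0.01 0.01 0.97 0.01\n0.01 0.01 0.01 0.97\n"
        )
        p = tmp_path / "m.meme"
        p.write_text(text)
        (pwm,) = read_meme_motifs(p)
        assert pwm.motif_id == "TEST1" and pwm.width == 4

    def test_uniform_background_default(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\nMOTIF X\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            "0.25 0.25 0.25 0.25\n"
        )
        (pwm,) = read_meme_motifs(p)
        assert pwm.background == pytest.approx([0.25] * 4)

    def test_background_parsed(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n"
            "Background letter frequencies\n"
            "A 0.3 C 0.2 G 0.2 T 0.3\n"
            "MOTIF X\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            "0.25 0.25 0.25 0.25\n"
        )
        (pwm,) = read_meme_motifs(p)
        assert pwm.background == pytest.approx([0.3, 0.2, 0.2, 0.3])

    def test_bad_row_sum(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\nMOTIF X\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            "0.5 0.5 0.5 0.5\n"
        )
        with pytest.raises(MemeParseError):
            read_meme_motifs(p)

    def test_roundtrip(self, tmp_path, rng):
        motifs = [random_pwm(rng, motif_id=f"m{i}") for i in range(5)]
        p = tmp_path / "rt.meme"
        write_meme_motifs(motifs, p)
        back = read_meme_motifs(p, pseudocount=0.0)
        assert len(back) == 5
        for orig, rt in zip(motifs, back):
            assert rt.motif_id == orig.motif_id
            assert np.allclose(rt.matrix, orig.matrix, atol=2e-6)


class TestScoreThreshold:
    def test_point_mass_enumeration(self):
        # exactly 1 of 256 words attains the full-match score
        pwm = point_mass_pwm("ACGT")
        threshold = score_threshold(pwm, 1 / 256)
        assert threshold == pytest.approx(pwm.max_score, abs=0.01)
        assert pwm.max_score == pytest.approx(8.0, abs=1e-4)

    def test_cutoff_out_of_range_rejected(self, rng):
        pwm = random_pwm(rng)
        with pytest.raises(ValueError):
            score_threshold(pwm, 0.0)
        with pytest.raises(ValueError):
            score_threshold(pwm, 1.1)

    def test_cutoff_one_is_minimum(self, rng):
        pwm = random_pwm(rng)
        threshold = score_threshold(pwm, 1.0)
        assert threshold <= pwm.min_score + 0.01

    def test_cutoff_below_best_word_warns(self):
        pwm = point_mass_pwm("ACGT")
        with pytest.warns(UserWarning, match="best word"):
            threshold = score_threshold(pwm, 1e-9)
        assert threshold == pytest.approx(pwm.max_score, abs=0.01)

    def test_distribution_matches_enumeration(self, rng):
        step = 1e-3
        for _ in range(12):
            pwm = random_pwm(rng, background=rng.dirichlet(np.ones(4) * 5))
            scores, probs = score_distribution(pwm, step=step)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            grid = np.rint(pwm.log_odds / step).astype(np.int64)
            word_scores = []
            word_probs = []
            for word in itertools.product(range(4), repeat=pwm.width):
                word_scores.append(sum(grid[k, b] for k, b in enumerate(word)) * step)
                word_probs.append(np.prod([pwm.background[b] for b in word]))
            word_scores = np.array(word_scores)
            word_probs = np.array(word_probs)
            for t in np.quantile(word_scores, [0.1, 0.5, 0.9, 0.99]):
                tail_bf = word_probs[word_scores >= t - 1e-9].sum()
                tail_dp = probs[scores >= t - 1e-9].sum()
                assert tail_dp == pytest.approx(tail_bf, abs=1e-9)


class TestScanSequence:
    def test_exact_match_plus(self):
        pwm = point_mass_pwm("ACGG")
        hits = scan_sequence(pwm, "TTACGGTT", threshold=pwm.max_score - 0.01)
        assert [(h[0], h[1]) for h in hits] == [(2, "+")]

    def test_exact_match_minus(self):
        pwm = point_mass_pwm("ACGG")
        hits = scan_sequence(pwm, "TTCCGTTT", threshold=pwm.max_score - 0.01)
        assert [(h[0], h[1]) for h in hits] == [(2, "-")]

    def test_short_sequence(self):
        pwm = point_mass_pwm("ACGG")
        assert scan_sequence(pwm, "AC", threshold=-100) == []

    def test_n_windows_skipped(self):
        pwm = point_mass_pwm("ACGG")
        # positions 0-2 touch the N at index 2 and are skipped
        hits = scan_sequence(pwm, "ACNGACGG", threshold=-1000)
        assert hits and all(h[0] >= 3 for h in hits)

    def test_brute_force_oracle(self, rng):
        for _ in range(60):
            pwm = random_pwm(rng)
            seq = "".join(
                rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=50)
            )
            threshold = float(rng.uniform(-3, 4))
            got = scan_sequence(pwm, seq, threshold)
            expected = brute_force_scan(pwm, seq, threshold)
            assert [(p, s) for p, s, _ in got] == [(p, s) for p, s, _ in expected]
            for g, e in zip(got, expected):
                assert g[2] == pytest.approx(e[2], abs=1e-9)


class TestHitsAroundCenters:
    def _setup(self, rng, word="ACGTGCGAT", n_rois=5, half_width=1500):
        length = 40_000
        seq = "".join(rng.choice(list("ACGT"), size=length))
        rois = []
        for i in range(n_rois):
            center = 3000 + i * 7000
            rois.append(
                ROI(
                    GenomicInterval("chr1", center - 750, center + 750, name=f"r{i}"),
                    center=center,
                )
            )
        return seq, rois

    def test_embedded_at_center(self, rng):
        word = "ACGTGCGAT"
        seq, rois = self._setup(rng)
        pwm = point_mass_pwm(word)
        center = rois[0].center
        start = center - len(word) // 2
        seq = seq[:start] + word + seq[start + len(word) :]
        hits = hits_around_centers({"chr1": seq}, [rois[0]], pwm, pwm.max_score - 0.01)
        assert len(hits) == 1
        assert hits[0].displacement == pytest.approx(0.5)  # midpoint of 9-mer
        assert hits[0].best

    def test_no_hits(self, rng):
        seq, rois = self._setup(rng)
        pwm = point_mass_pwm("ACGTGCGAT")
        # a threshold above the max score yields nothing
        hits = hits_around_centers({"chr1": seq}, rois, pwm, pwm.max_score + 1.0)
        assert hits == []

    def test_missing_chromosome(self, rng):
        seq, rois = self._setup(rng)
        pwm = point_mass_pwm("ACGT")
        bad = [ROI(GenomicInterval("chrX", 0, 100, name="x"), center=50)]
        with pytest.raises(KeyError, match="chrX"):
            hits_around_centers({"chr1": seq}, bad, pwm, 0.0)

    def test_displacement_sd_recovery(self):
        rng = np.random.default_rng(99)
        # width 12 keeps chance exact matches (~4^-12 per window) from
        # contaminating the displacement sample
        word = "ACGTGCGATCAG"
        pwm = point_mass_pwm(word)
        n = 500
        length = n * 4000 + 4000
        seq = list(rng.choice(list("ACGT"), size=length))
        rois = []
        displacements = []
        for i in range(n):
            center = 2000 + i * 4000
            d = float(np.clip(rng.normal(0, 150), -1400, 1400))
            start = int(center + d - len(word) // 2)
            seq[start : start + len(word)] = list(word)
            displacements.append(d)
            rois.append(
                ROI(GenomicInterval("chr1", center - 100, center + 100, name=f"r{i}"), center=center)
            )
        hits = hits_around_centers(
            {"chr1": "".join(seq)}, rois, pwm, pwm.max_score - 0.01
        )
        best = [h.displacement for h in hits if h.best]
        assert len(best) >= 0.95 * n
        assert np.std(best) == pytest.approx(150, rel=0.2)

    def test_best_hit_tie_smallest_displacement(self, rng):
        word = "ACGT"
        pwm = point_mass_pwm(word)
        center = 2000
        seq = list(rng.choice(list("ACGT"), size=4000))
        # two exact copies at displacements ~ -500 and ~ +100
        for d in (-500, 100):
            start = center + d - 2
            seq[start : start + 4] = list(word)
        roi = ROI(GenomicInterval("chr1", center - 750, center + 750, name="r"), center=center)
        hits = hits_around_centers({"chr1": "".join(seq)}, [roi], pwm, pwm.max_score - 0.01)
        best = [h for h in hits if h.best]
        assert len(best) == 1
        assert abs(best[0].displacement) == min(abs(h.displacement) for h in hits)


class TestMDDistribution:
    def _hit(self, d):
        return MotifHit("r", "m", 0, "+", 10.0, d)

    def test_all_zero_displacements(self):
        dist = md_distribution([self._hit(0.0) for _ in range(10)], n_bins=100)
        center_bin = 50  # displacement 0 falls in the bin right of center
        assert dist.fractions[center_bin] == pytest.approx(1.0)

    def test_fraction_sum(self, rng):
        hits = [self._hit(float(d)) for d in rng.uniform(-1500, 1500, size=100)]
        dist = md_distribution(hits)
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_bound(self):
        rng = np.random.default_rng(1)
        hits = [self._hit(float(d)) for d in rng.uniform(-1500, 1500, size=10_000)]
        dist = md_distribution(hits, n_bins=10)
        assert dist.fractions.max() <= 3 / 10

    def test_no_hits_flagged(self):
        dist = md_distribution([], motif_id="m")
        assert not dist.has_hits
        assert dist.fractions.sum() == 0.0

    def test_odd_bins_rejected(self):
        with pytest.raises(ValueError):
            md_distribution([], n_bins=7)


class TestEnrichmentScore:
    def test_hand_computed(self):
        # N = 4 is below the stability floor; compute by the formula at N=10
        # with hits at ranks 1 and 2, displacement 0:
        # e = ((1-2*0.05) + (1-2*0.15)) / 2 = (0.9 + 0.7)/2 = 0.8
        ids = [f"r{i}" for i in range(10)]
        score = enrichment_score(ids, {"r0": 0.0, "r1": 0.0})
        assert score == pytest.approx(0.8)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            enrichment_score(["a"] * 4, {"a": 0.0})

    def test_all_hit_equal_weight_zero(self):
        ids = [f"r{i}" for i in range(20)]
        score = enrichment_score(ids, {i: 0.0 for i in ids})
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversal_negates(self, rng):
        ids = [f"r{i}" for i in range(50)]
        hits = {
            i: float(rng.uniform(-300, 300)) for i in ids if rng.random() < 0.4
        }
        fwd = enrichment_score(ids, hits)
        rev = enrichment_score(ids[::-1], hits)
        assert fwd == pytest.approx(-rev)

    def test_bounds(self, rng):
        ids = [f"r{i}" for i in range(30)]
        for _ in range(20):
            hits = {
                i: float(rng.uniform(-1500, 1500)) for i in ids if rng.random() < 0.5
            }
            if not hits:
                continue
            assert -1.0 <= enrichment_score(ids, hits) <= 1.0

    def test_no_hits_zero(self):
        assert enrichment_score([f"r{i}" for i in range(10)], {}) == 0.0


@given(
    n_rois=st.integers(min_value=10, max_value=60),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=40, deadline=None)
def test_enrichment_score_bounded_and_relabel_invariant(n_rois, seed):
    rng = np.random.default_rng(seed)
    ids = [f"r{i}" for i in range(n_rois)]
    hits = {i: float(rng.uniform(-1500, 1500)) for i in ids if rng.random() < 0.5}
    score = enrichment_score(ids, hits)
    assert -1.0 <= score <= 1.0
    # relabeling ROI ids (keeping rank order and hit assignment) is a no-op
    renamed = {f"x{i}": ids[i] for i in range(n_rois)}
    new_ids = list(renamed.keys())
    new_hits = {new: hits[old] for new, old in renamed.items() if old in hits}
    assert enrichment_score(new_ids, new_hits) == pytest.approx(score)


class TestGcCorrect:
    def test_perfectly_linear(self):
        rows = [(f"m{i}", 0.1 + 0.5 * gc, gc) for i, gc in enumerate([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])]
        corrected = gc_correct(rows)
        assert all(abs(v) < 1e-12 for v in corrected.values())

    def test_constant_gc_mean_centering(self):
        rows = [(f"m{i}", e, 0.5) for i, e in enumerate([0.1, 0.2, 0.3, 0.4, 0.5])]
        corrected = gc_correct(rows)
        assert np.mean(list(corrected.values())) == pytest.approx(0.0, abs=1e-12)
        assert corrected["m0"] == pytest.approx(0.1 - 0.3)

    def test_residuals_sum_zero(self, rng):
        rows = [
            (f"m{i}", float(rng.normal()), float(rng.uniform(0.2, 0.8)))
            for i in range(30)
        ]
        corrected = gc_correct(rows)
        assert sum(corrected.values()) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_motifs_warns(self):
        rows = [("a", 0.5, 0.4), ("b", -0.1, 0.6)]
        with pytest.warns(UserWarning, match="fewer than 5"):
            corrected = gc_correct(rows)
        assert corrected == {"a": 0.5, "b": -0.1}


class TestMotifPvalues:
    def test_no_hit_motif_permutation_p_one(self):
        ids = [f"r{i}" for i in range(20)]
        res = motif_pvalues(
            {"m": 0.0},
            ranked=ids,
            best_hits_by_motif={"m": {}},
            mode="permutation",
            n_perm=100,
            seed=0,
        )
        assert res["m"][1] == pytest.approx(1.0)

    def test_permutation_deterministic(self, rng):
        ids = [f"r{i}" for i in range(100)]
        hits = {i: float(rng.uniform(-200, 200)) for i in ids if rng.random() < 0.3}
        kwargs = dict(
            ranked=ids,
            best_hits_by_motif={"m": hits},
            mode="permutation",
            n_perm=150,
            seed=42,
        )
        a = motif_pvalues({"m": 0.1}, **kwargs)
        b = motif_pvalues({"m": 0.1}, **kwargs)
        assert a == b

    def test_z_mode_zero_variance(self):
        with pytest.raises(ValueError, match="permutation"):
            motif_pvalues({"a": 0.5, "b": 0.5, "c": 0.5})

    def test_z_mode_basic(self):
        res = motif_pvalues({"a": 0.9, "b": 0.0, "c": -0.9, "d": 0.1, "e": -0.1})
        assert all(0 < v[1] <= 1 for v in res.values())
        assert all(v[2] >= v[1] for v in res.values())

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            motif_pvalues(
                {"m": 0.0},
                ranked=["r"] * 10,
                best_hits_by_motif={"m": {}},
                mode="permutation",
                n_perm=10,
            )
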