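import numpy as np
import pytest

from tfkinetics.regions import CountMatrix, GenomicInterval, ROI, SampleInfo, StrandedRead


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_interval(chrom="chr1", start=0, end=100, **kwargs):
    return GenomicInterval(chrom, start, end, **kwargs)


def make_read(chrom="chr1", start=0, end=30, strand="+", sample="s1"):
    return StrandedRead(GenomicInterval(chrom, start, end, strand=strand), sample_id=sample)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def nb_matrix(rng, means, dispersion, n_a=3, n_b=3, means_b=None):
    """CountMatrix with NB counts; means_b defaults to means (null)."""
    means = np.asarray(means, dtype=float)
    means_b = means if means_b is None else np.asarray(means_b, dtype=float)
    r = 1.0 / dispersion
    ka = rng.negative_binomial(r, r / (r + means[:, None]), size=(len(means), n_a))
    kb = rng.negative_binomial(r, r / (r + means_b[:, None]), size=(len(means), n_b))
    samples = [SampleInfo(f"a{i}", "A") for i in range(n_a)] + [
        SampleInfo(f"b{i}", "B") for i in range(n_b)
    ]
    features = [f"f{i:05d}" for i in range(len(means))]
    return CountMatrix(features, samples, np.hstack([ka, kb]))


GROUP_A = [f"a{i}" for i in range(3)]
GROUP_B = [f"b{i}" for i in range(3)]
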