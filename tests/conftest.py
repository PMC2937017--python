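import numpy as np
import pytest

from cnakit.genome_io import CopyNumberProfile, GenomeBuild, Segment


@pytest.fixture
def build():
    return GenomeBuild.from_dict({"chr1": 100_000_000, "chr2": 80_000_000})


def make_profile(sample_id, chrom, pieces):
    """pieces: iterable of (start, end, n_probes, log2) on one chromosome."""
    return CopyNumberProfile(
        sample_id,
        [Segment(sample_id, chrom, s, e, p, l) for s, e, p, l in pieces],
    )


def random_contiguous_profile(rng, sample_id="S", chrom="chr1", length=10_000_000,
                              max_segments=8):
    """A gap-free random profile over [0, length)."""
    k = rng.integers(1, max_segments + 1)
    cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    pieces = [
        (s, e, int(rng.integers(1, 50)), float(rng.normal(0, 0.6)))
        for s, e in zip(bounds, bounds[1:])
    ]
    return make_profile(sample_id, chrom, pieces)
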