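import numpy as np
import pandas as pd
import pytest

from nucleodyn import genome_io as gio
from nucleodyn import occupancy as oc
from nucleodyn import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_index():
    return gio.GenomeIndex(("chr1", "chr2"), (100_000, 60_000))


@pytest.fixture(scope="session")
def null_study():
    """A 12-Mbp homogeneous genome sampled twice at ~200 fragments / 5-kbp window.

    No planted events: both time points are independent draws from the same
    landscape, so every window is null.  Shared across calibration tests.
    """
    spec = sim.LandscapeSpec(genome_length=12_000_000, seed=7)
    track = sim.simulate_landscape(spec, genes=None)
    # 200 fragments per 5-kbp window = 200/5000*190 ≈ 7.6 fragments/nucleosome
    occupancy = 200 / 5_000 * spec.nrl
    frags1 = sim.sample_fragments(track, occupancy, seed=np.random.default_rng(71))
    frags2 = sim.sample_fragments(track, occupancy, seed=np.random.default_rng(72))
    grid = oc.tile_genome(spec.index, 5_000)
    return {
        "spec": spec,
        "grid": grid,
        "mid1": sim.fragments_to_midpoints(frags1),
        "mid2": sim.fragments_to_midpoints(frags2),
    }


@pytest.fixture
def gene_frame():
    """Two genes on chr1: + strand [20000,30000), − strand [50000,62000)."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [20_000, 50_000],
            "end": [30_000, 62_000],
            "name": ["geneA", "geneB"],
            "score": [0, 0],
            "strand": ["+", "-"],
            "tss": [20_000, 61_999],
            "tts": [29_999, 50_000],
        }
    )
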