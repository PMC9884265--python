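import numpy as np
import pandas as pd
import pytest

from heatloop.core import GenomeLayout, GeneAnnotation
from heatloop.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def preset_ds():
    """The paper-like preset at seed 1, shared across tests."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def tiny_layout():
    return GenomeLayout((("c1", 1_000_000),), {"c1": (400_000, 600_000)}, bin_size=10_000)


@pytest.fixture(scope="session")
def small_genes():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["c1", "c1", "c1"],
        "start": [50_000, 120_000, 300_000],
        "end": [53_000, 124_000, 302_000],
        "strand": ["+", "-", "+"],
    }))


def loop_construction(seed, fold=4.0):
    """Spec-style loop-recovery construction: decay-only background, planted
    loops of the given fold, C-Hi-C capture bias."""
    cfg = SynthConfig(amplitude=0.0, gained_fold=fold, stable_fold=fold,
                      aa_boost=1.0, bb_damp=1.0,
                      contact_assays=(("CHiC", "1h"),),
                      generate_sequences=False, generate_fine_tracks=False)
    return generate_dataset(cfg, seed=seed)


def sample_nonloop_pairs(ds, n, seed, min_d=2, max_d=100):
    rng = np.random.default_rng(seed)
    loops = {(l.chrom, min(l.bin1, l.bin2), max(l.bin1, l.bin2)) for l in ds.truth.loops}
    n_bins = ds.layout.n_bins(ds.layout.names[0])
    out = []
    while len(out) < n:
        c = ds.layout.names[int(rng.integers(len(ds.layout.names)))]
        i = int(rng.integers(0, n_bins))
        j = int(rng.integers(0, n_bins))
        i, j = min(i, j), max(i, j)
        key = (c, i, j)
        if min_d <= j - i <= max_d and key not in loops and key not in out:
            out.append(key)
    return out
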