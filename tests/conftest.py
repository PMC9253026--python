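import numpy as np
import pytest

from strainpop.config import CommunityConfig, FilterConfig
from strainpop.filtering import build_pileup, filter_read_pairs
from strainpop.synthetic import simulate_community


@pytest.fixture(scope="session")
def small_community():
    """One 20 kb bin, two populations, one sample each, 40x."""
    cfg = CommunityConfig(
        seed=1234, n_bins=1, genome_length=20_000, depth=40,
        samples_per_population=1,
    )
    reference, truth, samples = simulate_community(cfg)
    return cfg, reference, truth, samples


@pytest.fixture(scope="session")
def small_pileups(small_community):
    cfg, reference, truth, samples = small_community
    fc = FilterConfig()
    piles, masks = {}, {}
    for name, rs in samples.items():
        mask, _ = filter_read_pairs(rs, fc, reference.sequences)
        masks[name] = mask
        piles[name] = build_pileup(rs, mask, fc)
    return piles, masks
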