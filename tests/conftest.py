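import pytest

from synscaf.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_sim():
    """A noise-free simulated dataset: every anchor is correct."""
    cfg = SimConfig(seed=1, spurious_rate=0.0, anchor_missing_rate=0.0)
    reference, contigs, truth, hits, flank_hits = simulate_dataset(cfg)
    return {
        "config": cfg,
        "reference": reference,
        "contigs": contigs,
        "truth": truth,
        "hits": hits,
        "flank_hits": flank_hits,
    }


@pytest.fixture(scope="session")
def noisy_sim():
    """Default noise levels plus an elevated spurious-hit rate."""
    cfg = SimConfig(seed=1, spurious_rate=0.05)
    reference, contigs, truth, hits, flank_hits = simulate_dataset(cfg)
    return {
        "config": cfg,
        "reference": reference,
        "contigs": contigs,
        "truth": truth,
        "hits": hits,
        "flank_hits": flank_hits,
    }
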