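import numpy as np
import pytest

from phylosdm import seqio, synthetic


@pytest.fixture
def toy_alignment():
    """4 sequences, 2 variable sites: haplotypes AA, AA, AT, TT."""
    seqs = {"s1": "AA", "s2": "AA", "s3": "AT", "s4": "TT"}
    return seqio.Alignment(tuple(seqs), tuple(seqs.values()))


@pytest.fixture
def toy_popmap(toy_alignment):
    ids = toy_alignment.sample_ids
    return seqio.PopulationMap(
        {s: "P1" for s in ids}, {s: 100.0 for s in ids}, {s: 45.0 for s in ids}
    )


@pytest.fixture
def cer1502_like():
    return synthetic.make_fixture("cer1502-like")


@pytest.fixture
def extirpation_toy():
    return synthetic.make_fixture("extirpation-toy")


@pytest.fixture
def two_cluster():
    return synthetic.make_fixture("two-cluster")


@pytest.fixture(scope="session")
def small_sdm_data():
    """Synthetic landscape + occurrences at desk scale (shared across tests)."""
    from phylosdm.sdm import sample_background

    cfg = synthetic.SimConfig(seed=11, n_layers=4)
    current, _ = synthetic.simulate_rasters(cfg)
    suit = synthetic.true_suitability(cfg, current)
    occ = synthetic.sample_occurrences(suit, current, 40, seed=12)
    bg = sample_background(current, 1000, seed=13)
    return {"cfg": cfg, "stack": current, "truth": suit, "occ": occ, "bg": bg}
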