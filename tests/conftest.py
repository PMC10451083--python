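import numpy as np
import pytest

from pedsweep import synthetic_data as sd


@pytest.fixture
def small_config():
    return sd.SimConfig(
        n_chrom=2,
        markers_per_chrom=300,
        chrom_len_bp=3_000_000,
        chrom_len_cM=100.0,
        delta=0.6,
        n_descendants=10,
        n_candidates_per_cycle=30,
        n_cycles=2,
        selected_loci=[sd.SelectedLocus("chr1", 1_500_000, 3.0, 1)],
        dh_n=60,
        qtls=[sd.QTLSpec("yield", "chr1", 30.0, 1.0)],
        h2={"yield": 0.6},
        seed=11,
    )


@pytest.fixture
def neutral_config():
    return sd.SimConfig(
        n_chrom=1,
        markers_per_chrom=200,
        chrom_len_bp=2_000_000,
        chrom_len_cM=100.0,
        delta=1.0,
        n_descendants=12,
        n_cycles=0,
        dh_n=40,
        seed=5,
    )


@pytest.fixture
def panel(small_config):
    rng = np.random.default_rng(small_config.seed)
    founders = sd.make_founders(small_config, np.random.default_rng(small_config.seed))
    gm, truth = sd.simulate_descendants(small_config, rng, founders=founders)
    return founders, gm, truth
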