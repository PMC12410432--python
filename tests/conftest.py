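import pytest

from radymap.simulate import SimConfig


@pytest.fixture
def tiny_config():
    """Small, fast study: 3 chromosomes, sparse map, few samples."""
    return SimConfig(
        n_chromosomes=3,
        loci_per_chromosome=8,
        chrom_length_cM=50.0,
        y_region_span_cM=5.0,
        n_y_loci=4,
        n_males=10,
        n_females=10,
        n_offspring=60,
        paralog_pairs=2,
        n_noise_snps=6,
        sex_chromosome_index=2,
        seed=7,
    )


@pytest.fixture
def noise_free_config(tiny_config):
    import dataclasses

    return dataclasses.replace(
        tiny_config, dropout_rate=0.0, contamination_rate=0.0,
        geno_missing_rate=0.0,
    )
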