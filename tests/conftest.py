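import pytest

from multik.simulate import QualityProfile, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale simulation: 30 loci, 3 k-assemblies, 4000 read pairs."""
    return SimulationConfig(
        seed=11,
        n_loci=30,
        kmer_list=(21, 29, 41),
        n_read_pairs=4000,
        length_range=(100, 2000),
    )


@pytest.fixture(scope="session")
def clean_deep_config() -> SimulationConfig:
    """Full capture, no truncation, deep uniform coverage, no rRNA: the
    regime where every merged transcript maps 1:1 to a truth locus and
    chimera junctions are flanked by depth well above 30."""
    return SimulationConfig(
        seed=5,
        n_loci=20,
        kmer_list=(21, 29, 41),
        capture_prob_per_k=1.0,
        truncation_frac_range=(1.0, 1.0),
        chimera_rate=0.15,
        rrna_frac=0.0,
        expression_shape=0.2,
        n_read_pairs=15_000,
        length_range=(150, 1200),
        quality_profile=QualityProfile(mean_start=38.0, decay_per_cycle=0.1, read_sd=0.0, sd=1.0),
    )
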