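import pytest

from ervchip import (
    AlignedSample,
    EnrichmentSpec,
    GenomeModel,
    Placement,
    RepeatRecord,
    build_toy_genome,
    default_toy_config,
    simulate_chip_experiment,
)
from ervchip.simdata import RepeatFamilySpec, ToyGenomeConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """The default study-design toy genome (~1.2 Mb, mouse ERV/LINE families)."""
    return build_toy_genome(default_toy_config(seed=11))


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """One 100 kb chromosome with a handful of planted repeats."""
    return build_toy_genome(
        ToyGenomeConfig(
            chrom_sizes={"chr1": 100_000},
            repeat_families=[
                RepeatFamilySpec("IAPEz-int", "LTR", "ERVK", 10, 500),
                RepeatFamilySpec("L1_Mus", "LINE", "L1", 8, 600),
            ],
            n_genes=3,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def chip_input_pair(toy_genome):
    """A planted-enrichment ChIP channel plus a matched uniform input."""
    chip = simulate_chip_experiment(
        toy_genome,
        EnrichmentSpec(
            n_reads=60_000, factors={"IAPEz-int": 8.0, "VL30": 4.0},
            seed=21, sample_id="chip", role="chip",
        ),
    )
    inp = simulate_chip_experiment(
        toy_genome,
        EnrichmentSpec(n_reads=60_000, factors={}, seed=22, sample_id="input", role="input"),
    )
    return chip, inp


def make_sample(placements, sample_id="s", role="chip") -> AlignedSample:
    """Build an AlignedSample from (chrom, start, strand[, length]) tuples."""
    ps = [Placement(*p) if not isinstance(p, Placement) else p for p in placements]
    return AlignedSample(sample_id, role, ps, len(ps))


@pytest.fixture
def uniform_flat_genome() -> GenomeModel:
    return GenomeModel({"chr1": 20_000})
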