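import numpy as np
import pytest

from convergetrend.genesets import GeneSetCollection, GeneSetRecord, GeneUniverse
from convergetrend.synthetic_data import (
    NetworkSpec,
    ScenarioConfig,
    SetSpec,
    generate_scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def universe20():
    return GeneUniverse(frozenset(f"g{i:02d}" for i in range(20)))


@pytest.fixture
def small_universe():
    genes = [f"g{i:03d}" for i in range(200)]
    rng = np.random.default_rng(0)
    lengths = {g: int(l) for g, l in zip(genes, rng.integers(100, 5000, len(genes)))}
    mf = {g: float(m) for g, m in zip(genes, rng.integers(0, 20, len(genes)))}
    return GeneUniverse(frozenset(genes), cds_length=lengths, multifunctionality=mf)


def tiny_scenario_config(**overrides):
    """A fast scenario: 7 sets over 600 genes, light property battery."""
    defaults = dict(
        n_genes=600,
        core_size=80,
        set_specs=tuple(
            [SetSpec(f"s{i}", 30, "strong" if i < 2 else "weak", 2.0 + i)
             for i in range(4)]
            + [SetSpec(f"c{i}", 30, "null_control") for i in range(3)]
        ),
        n_properties=12,
        n_planted=4,
        n_score_properties=3,
        n_planted_score=1,
        signal_slope=0.15,
        signal_base=0.3,
        property_size_range=(30, 60),
        network_spec=NetworkSpec(n_modules=1, module_size=40, artifact_size=50),
        seed=3,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def tiny_scenario():
    return generate_scenario(tiny_scenario_config())


@pytest.fixture
def default_style_records(small_universe):
    """An 11-record collection shaped like the default study (tiny gene sets)."""
    from convergetrend.synthetic_data import default_set_specs

    genes = sorted(small_universe.genes)
    rng = np.random.default_rng(1)
    records = []
    for spec in default_set_specs():
        members = frozenset(rng.choice(genes, size=10, replace=False))
        records.append(
            GeneSetRecord(spec.id, members, spec.variant_class,
                          spec.effect_size, spec.tiebreak_key,
                          swappable=spec.swappable)
        )
    return GeneSetCollection(records, small_universe)
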