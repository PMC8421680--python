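import numpy as np
import pytest

from satkit.simulate import SimulationConfig, build_monomer, simulate_satdna


@pytest.fixture(scope="session")
def default_monomer():
    """Ancestral two-subunit monomer built under default conditions."""
    monomer, sub_a, sub_b, ident = build_monomer(SimulationConfig(seed=1))
    return {"monomer": monomer, "a": sub_a, "b": sub_b, "identity": ident}


@pytest.fixture(scope="session")
def small_sim():
    """One forward-strand array of 30 alternating units in a small contig."""
    cfg = SimulationConfig(
        seed=11,
        hor_pattern="(AB)x15",
        n_arrays=1,
        array_strands=("+",),
        satellite_fraction=0.10,
        n_monomers=20,
    )
    return cfg, simulate_satdna(cfg)


@pytest.fixture(scope="session")
def monomer_set_sim():
    """66 monomer copies at 2% substitution (no indels) plus their truth."""
    cfg = SimulationConfig(seed=9, monomer_indel_rate=0.0)
    return cfg, simulate_satdna(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
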