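import numpy as np
import pytest

from sitemut import Genome, SimulationSpec, simulate_cohort, simulate_genome, simulate_sites


@pytest.fixture(scope="session")
def toy_genome():
    """10 kb seeded random genome used by the brute-force oracle tests."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
    return Genome.from_sequences({"chr1": seq}), seq


def small_spec(seed=1, **kw):
    """Sub-megabase cohort spec for fast unit tests (rate window shrunk so
    sites fit the toy chromosome)."""
    defaults = dict(
        genome_length=400_000,
        n_sites=800,
        half_width=25,
        n_tumours=10,
        mean_rate=2000.0,
        rate_window=100_000,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


@pytest.fixture()
def small_cohort():
    spec = small_spec()
    g = simulate_genome(spec)
    sites = simulate_sites(spec, g)
    ms, truth = simulate_cohort(spec, g, sites)
    return spec, g, sites, ms, truth


@pytest.fixture(scope="session")
def null_cohort_medium():
    """One default-condition null cohort, shared by calibration-flavoured tests."""
    spec = SimulationSpec(seed=11)
    g = simulate_genome(spec)
    sites = simulate_sites(spec, g)
    ms, truth = simulate_cohort(spec, g, sites)
    return spec, g, sites, ms, truth
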