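import pytest

from aifquant.spectra_io import default_bile_acid_library
from aifquant.synthgen import SimCompound, SimConfig, simulate_run


@pytest.fixture(scope="session")
def library():
    return default_bile_acid_library()


@pytest.fixture(scope="session")
def by_name(library):
    return {e.name: e for e in library}


@pytest.fixture(scope="session")
def analytes(library):
    return [e for e in library if not e.is_internal_standard]


@pytest.fixture(scope="session")
def spiked_run(library, analytes):
    """One noisy run with all 26 bile-acid analytes at 0.5 µM plus the
    internal standards at their nominal concentration."""
    sim = [SimCompound(e, 0.5) for e in analytes]
    sim += [
        SimCompound(e, e.nominal_is_concentration)
        for e in library
        if e.is_internal_standard
    ]
    run, truth = simulate_run(
        sim,
        SimConfig(
            seed=11,
            rt_start=1.5,
            run_length=13.0,
            noise_floor=50.0,
            proportional_noise=0.02,
        ),
    )
    return run, truth
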