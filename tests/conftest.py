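import pytest

from swathlib import (FragmentIon, PrecursorEntry, SimConfig,
                      SpectralLibrary, simulate_library)


def make_entry(seq="ALSPEVK", modified=None, charge=2, mz=None, rt=10.0,
               protein="P1", confidence=0.99, decoy=False, shared=False,
               n_fragments=6, sources=("liver",)):
    """Hand-built precursor with schematic (but valid) fragment values."""
    fragments = [
        FragmentIon(mz=200.0 + 50.0 * i, relative_intensity=1000.0 - 10 * i,
                    series="y" if i % 2 == 0 else "b",
                    ordinal=1 + i % (len(seq) - 1), charge=1)
        for i in range(n_fragments)
    ]
    return PrecursorEntry(
        stripped_sequence=seq,
        modified_sequence=modified if modified is not None else seq,
        precursor_charge=charge,
        precursor_mz=mz if mz is not None else 400.0 + len(seq),
        rt=rt, protein=protein, confidence=confidence, is_decoy=decoy,
        shared=shared, sources=set(sources), fragments=fragments)


def make_library(entries, label="test"):
    return SpectralLibrary(entries, label=label)


@pytest.fixture(scope="session")
def sim_pair():
    """A moderately sized simulated library with its truth record."""
    return simulate_library(SimConfig(n_proteins=300, seed=42))


@pytest.fixture(scope="session")
def sim_lib(sim_pair):
    return sim_pair[0]


@pytest.fixture(scope="session")
def sim_truth(sim_pair):
    return sim_pair[1]
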