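import numpy as np
import pytest

from fluorscreen.curation import MoleculeRecord, PhotophysicalMeasurement


def M(prop, value, solvent="O"):
    return PhotophysicalMeasurement(prop, value, solvent)


@pytest.fixture
def curation_fixture_records():
    """Twelve raw records crafted so every curation rule fires exactly once.

    Expected survivors: the benzene record (labels merged from two duplicate
    spellings) and the pyridine record with its two consistent emission
    replicates averaged to 501.5 nm.
    """
    return [
        MoleculeRecord("C1CC"),                                   # unparsable
        MoleculeRecord("c1ccccc1", fluorescence_label="fluorescent",
                       condition=(400.0, 500.0)),
        MoleculeRecord("C1=CC=CC=C1", fluorescence_label="fluorescent",
                       condition=(400.0, 500.0)),                 # duplicate of above
        MoleculeRecord("CCO", fluorescence_label="fluorescent"),
        MoleculeRecord("OCC", fluorescence_label="non-fluorescent"),  # conflict pair
        MoleculeRecord("CC=O", measurements=[
            M("plqy", 1.2),                                       # yield > 1
            M("abs_wavelength", 1600.0),                          # outside 200-1500 nm
            M("log10_eps", 7.5),                                  # log eps > 7
        ]),
        MoleculeRecord("CCN", measurements=[M("em_wavelength", 450.0, None)]),
        MoleculeRecord("CCC", measurements=[M("em_wavelength", 450.0, "gas")]),
        MoleculeRecord("c1ccncc1", measurements=[M("em_wavelength", 500.0)]),
        MoleculeRecord("c1ccncc1", measurements=[M("em_wavelength", 503.0)]),
        MoleculeRecord("CCOCC", measurements=[M("em_wavelength", 500.0)]),
        MoleculeRecord("CCOCC", measurements=[M("em_wavelength", 520.0)]),
    ]


@pytest.fixture(scope="session")
def small_library():
    """A 60-molecule synthetic library (fast, deterministic)."""
    from fluorscreen.synthdata import GeneratorSpec, generate_library

    return generate_library(GeneratorSpec(n=60, seed=7))
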