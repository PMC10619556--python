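import numpy as np
import pytest

from biotransnet.chemcore import default_library, parse_formula
from biotransnet.msio import Ms2Spectrum


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {t.name: t for t in library}


@pytest.fixture(scope="session")
def t3_formula():
    # 3,3',5-triiodo-L-thyronine
    return parse_formula("C15 H12 I3 N O4")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_spectrum(feature_id, precursor_mz, peaks, charge=1):
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    return Ms2Spectrum(
        feature_id=feature_id, precursor_mz=precursor_mz, charge=charge,
        mz=np.array(mz, float), intensity=np.array(inten, float),
    )


@pytest.fixture
def spectrum_factory():
    return make_spectrum
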