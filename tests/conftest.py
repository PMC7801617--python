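import pytest

from mutriage import data

# Printed reference rows for the bundled talin-1 catalog: id -> (domain,
# location class, between-helices flag, pathogenicity probability,
# normalized BLOSUM62, normalized CBSM60, normalized conservation,
# published final score).
TALIN1_REFERENCE_ROWS = {
    "P229L": ("F2", "buried", 1, 0.94, 1.0, 1.0, 1.0, 8.20),
    "I392N": ("F3", "buried", 0, 0.86, 1.0, 0.83, 1.0, 8.95),
    "V577D": ("R1", "buried", 0, 0.94, 1.0, 1.0, 0.60, 8.39),
    "A893E": ("R3", "buried", 1, 0.95, 0.75, 0.33, 0.60, 7.63),
    "R1368W": ("R7", "surface", 0, 0.98, 1.0, 1.0, 1.0, 7.75),
    "Y1389C": ("R7", "buried", 0, 0.90, 0.87, 0.67, 1.0, 8.58),
    "L1539P": ("R8", "buried", 0, 0.98, 1.0, 1.0, 0.60, 8.45),
    "S1750F": ("R9", "buried", 0, 0.89, 0.87, 0.5, 0.60, 7.55),
    "E1770Q": ("R9", "surface", 0, 0.81, 0.37, -0.33, 1.0, 6.01),
    "D2086V": ("R11", "surface", 0, 0.96, 1.0, 1.0, 1.0, 7.71),
    "L2509P": ("DD", "surface", 0, 0.96, 1.0, 1.0, 0.64, 7.46),
}


@pytest.fixture(scope="session")
def bundle():
    return data.talin1_bundle()


@pytest.fixture(scope="session")
def matrices(bundle):
    return bundle.matrices


@pytest.fixture(scope="session")
def reference_rows():
    return TALIN1_REFERENCE_ROWS
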