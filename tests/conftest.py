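import numpy as np
import pytest

from empaiq.quantification import QuantRecord

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


def random_protein(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


@pytest.fixture(scope="session")
def small_proteins(rng):
    """100 random small proteins for oracle-equivalence sweeps."""
    return [random_protein(rng, int(rng.integers(10, 51))) for _ in range(100)]


def qrec(accession, strain, values):
    return QuantRecord.from_values(accession, strain, values)


@pytest.fixture()
def planted_quant():
    """140 shared proteins: 21 planted increased, 23 decreased, 96 constant.

    Per-run emPAI values carry a small deterministic ripple so the t-test
    is defined (nonzero within-strain variance).
    """
    ripple = [-0.1, 0.0, 0.1, -0.1, 0.0, 0.1]
    test, ref = {}, {}
    k = 0
    for i in range(21):
        acc = f"P{k:03d}"
        test[acc] = qrec(acc, "B", [5.0 + r for r in ripple])
        ref[acc] = qrec(acc, "A", [1.0 + r for r in ripple])
        k += 1
    for i in range(23):
        acc = f"P{k:03d}"
        test[acc] = qrec(acc, "B", [1.0 + r for r in ripple])
        ref[acc] = qrec(acc, "A", [5.0 + r for r in ripple])
        k += 1
    for i in range(96):
        acc = f"P{k:03d}"
        test[acc] = qrec(acc, "B", [2.0 + r for r in ripple])
        ref[acc] = qrec(acc, "A", [2.0 + r for r in ripple])
        k += 1
    return test, ref
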