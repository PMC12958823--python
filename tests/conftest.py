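import numpy as np
import pandas as pd
import pytest

from pinesem.pedigree import Pedigree


@pytest.fixture(scope="session")
def half_sib_pedigree():
    """25 open-pollinated families of 8 offspring from 30 founders."""
    rows = [{"id": f"F{i:02d}", "sire": "", "dam": "", "group": str(i % 2 + 1)}
            for i in range(30)]
    rows += [{"id": f"T{i:03d}", "sire": "", "dam": f"F{i // 8:02d}",
              "group": str((i // 8) % 2 + 1)}
             for i in range(200)]
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_pedigree():
    """Founders S, D plus a parent-offspring mating and sib structures."""
    rows = [
        {"id": "S", "sire": "", "dam": "", "group": "1"},
        {"id": "D", "sire": "", "dam": "", "group": "1"},
        {"id": "A", "sire": "S", "dam": "D", "group": "1"},
        {"id": "B", "sire": "S", "dam": "D", "group": "1"},
        {"id": "C", "sire": "S", "dam": "A", "group": "1"},
    ]
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
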