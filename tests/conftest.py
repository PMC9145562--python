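import numpy as np
import pandas as pd
import pytest

from antmorph import (
    SpecimenTable,
    TRAIT_CODES,
    default_study_scenario,
    generate,
)


def make_table(cell_sizes, seed=0, base=500.0, species_gap=100.0,
               infection_shift=0.0, noise=5.0):
    """Hand-rolled specimen table: ``cell_sizes`` maps species name to
    (n_uninfected, n_infected); traits are base + species offset + iid
    noise + infection shift (in raw units).  Independent of the synth
    module so it can serve as a fixture for testing it."""
    rng = np.random.default_rng(seed)
    rows = []
    for si, (species, (n_un, n_inf)) in enumerate(sorted(cell_sizes.items())):
        for j in range(n_un + n_inf):
            infected = j >= n_un
            row = {
                "specimen_id": f"{species}-{j}",
                "species": species,
                "infected": infected,
            }
            for t in TRAIT_CODES:
                row[t] = (base + si * species_gap
                          + rng.normal(0.0, noise)
                          + (infection_shift if infected else 0.0))
            rows.append(row)
    return SpecimenTable.from_dataframe(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def study_table():
    """One draw of the study-like scenario: 81 specimens, 3 species."""
    return generate(default_study_scenario(seed=7))


@pytest.fixture
def tiny_table():
    """Two species, 3+3 specimens each, mild infection effect."""
    return make_table({"sp_a": (3, 3), "sp_b": (3, 3)}, seed=1,
                      infection_shift=-10.0)
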