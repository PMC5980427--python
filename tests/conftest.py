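import numpy as np
import pytest

from hzkit.io_formats import GenotypePanel
from hzkit.synthetic_data import default_study_fixture, make_landscape


def make_panel(pop_genotypes: dict[str, list], locus_names=None, species=None):
    """Assemble a GenotypePanel from {pop: [[(a,b) per locus], ...]}."""
    ids, pops, sps, genos = [], [], [], []
    for pop, inds in pop_genotypes.items():
        for i, g in enumerate(inds):
            ids.append(f"{pop}_{i}")
            pops.append(pop)
            sps.append((species or {}).get(pop, "unknown"))
            genos.append(g)
    genos = np.asarray(genos)
    return GenotypePanel(
        ids,
        pops,
        sps,
        np.zeros(len(ids), dtype=bool),
        genos,
        locus_names or [f"L{i + 1}" for i in range(genos.shape[1])],
    )


@pytest.fixture(scope="session")
def study_fixture():
    """The default calibrated 237-individual study panel (seed-fixed)."""
    return default_study_fixture(seed=1)


@pytest.fixture(scope="session")
def landscape():
    return make_landscape(n_rows=60, n_cols=80, seed=2)
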