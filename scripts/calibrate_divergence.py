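"""Monte-Carlo calibration of the species-level drift parameter.

Finds the Dirichlet drift F for which two 30-sample species panels at the
default 12 microsatellite-like loci give a mean Weir-Cockerham theta near
the 0.25 between-species anchor.  The selected value is frozen as
``hzkit.synthetic_data.DEFAULT_DIVERGENCE_F``.

Run:  python scripts/calibrate_divergence.py
"""

import numpy as np

from hzkit.io_formats import GenotypePanel
from hzkit.popgen_stats import wc_theta
from hzkit.synthetic_data import (
    SpeciesFreqModel,
    make_parental_frequencies,
    sample_population_genotypes,
)


def realized_fst(F: float, seed: int, n: int = 30) -> float:
    model = SpeciesFreqModel.default(seed=seed, divergence_F=F)
    freqs = make_parental_frequencies(model, seed=seed + 1000)
    rng = np.random.default_rng(seed + 2000)
    pe = sample_population_genotypes(
        list(zip(model.allele_codes, freqs["Ie"])), n, rng, population="E"
    )
    pg = sample_population_genotypes(
        list(zip(model.allele_codes, freqs["Ig"])), n, rng, population="G"
    )
    theta, _ = wc_theta(GenotypePanel.concatenate([pe, pg]))
    return theta


if __name__ == "__main__":
    seeds = range(20)
    for F in (0.10, 0.14, 0.17, 0.19, 0.21, 0.23, 0.25, 0.30):
        vals = [realized_fst(F, s) for s in seeds]
        print(
            f"F={F:.2f}  mean theta={np.mean(vals):.3f}  sd={np.std(vals):.3f}  "
            f"range=({min(vals):.3f}, {max(vals):.3f})"
        )
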