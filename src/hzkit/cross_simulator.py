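"""Simulation of F1 hybrids and serial backcross genotype classes.

Artificial hybrid panels are built from two parental reference pools
(*I. elegans* "Ie" and *I. graellsii* "Ig" by default).  Serial classes are
generated recursively: F1 from the two species pools, 1EB from F1 x elegans,
2EB from 1EB x elegans, and so on; mirror classes backcross into graellsii.

Two transmission modes are provided.  ``individual_mendelian`` (default)
samples a concrete parent individual and transmits one of its two alleles
per locus, preserving within-individual associations.  ``frequency_draw``
samples each transmitted allele from the parent class's pooled allele
frequencies, the behaviour of frequency-based hybrid simulators.

Each simulated allele copy carries a tracked elegans-lineage bit, so
pedigree expectations (F1 = 0.5, kEB = 1 - 2^-(k+1), kGB = 2^-(k+1)) can be
verified directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypePanel

__all__ = [
    "CROSS_CLASSES",
    "TABLE_CLASS_SET",
    "METHODS_CLASS_SET",
    "CrossPanel",
    "expected_e_ancestry",
    "gamete_e_probability",
    "estimate_pool",
    "simulate_cross",
    "build_cross_panel",
]

#: class name -> (parent_a, parent_b); "E"/"G" denote the species pools
CROSS_CLASSES: dict[str, tuple[str, str]] = {
    "F1": ("E", "G"),
    "1EB": ("F1", "E"),
    "2EB": ("1EB", "E"),
    "3EB": ("2EB", "E"),
    "4EB": ("3EB", "E"),
    "1GB": ("F1", "G"),
    "2GB": ("1GB", "G"),
    "3GB": ("2GB", "G"),
}

#: the seven classes of the results tables (350 genotypes at 50 each)
TABLE_CLASS_SET = ("F1", "1GB", "2GB", "3GB", "1EB", "2EB", "3EB")
#: the six classes listed in the methods text (includes 4EB, no 2GB/3GB)
METHODS_CLASS_SET = ("F1", "1EB", "1GB", "2EB", "3EB", "4EB")


def expected_e_ancestry(name: str) -> float:
    """Pedigree-expected fraction of elegans ancestry for a cross class."""
    if name == "E":
        return 1.0
    if name == "G":
        return 0.0
    if name == "F1":
        return 0.5
    if name.endswith("EB"):
        k = int(name[:-2])
        return 1.0 - 2.0 ** -(k + 1)
    if name.endswith("GB"):
        k = int(name[:-2])
        return 2.0 ** -(k + 1)
    raise KeyError(f"unknown cross class {name!r}")


def gamete_e_probability(name: str) -> float:
    """Probability a gamete copy from this class carries elegans lineage.

    For unlinked loci a gamete from class C is elegans at each locus
    independently with probability equal to C's expected ancestry.
    """
    return expected_e_ancestry(name)


@dataclass
class CrossPanel:
    """A genotype panel of simulated crosses with per-copy lineage tracking."""

    panel: GenotypePanel
    class_label: list[str]
    #: (n, n_loci, 2) of 1.0 where the copy descends from the elegans pool
    ancestry: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.class_label) != self.panel.n_individuals:
            raise ValueError("class label per individual required")
        if self.ancestry is not None:
            self.ancestry = np.asarray(self.ancestry, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.panel.n_individuals

    def tracked_e_ancestry(self) -> np.ndarray:
        """Per-individual mean elegans lineage over all allele copies."""
        return self.ancestry.mean(axis=(1, 2))

    def class_members(self, name: str) -> np.ndarray:
        return np.array([c == name for c in self.class_label])


# ---------------------------------------------------------------------------
# parental material
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPool:
    """Per-locus allele frequencies of a parental species."""

    species_label: str
    alleles: list[np.ndarray]  # allele codes per locus
    freqs: list[np.ndarray]  # matching frequencies (sum to 1)
    e_ancestry: float  # 1.0 for the elegans pool, 0.0 for graellsii

    @property
    def n_loci(self) -> int:
        return len(self.alleles)


def estimate_pool(
    panel: GenotypePanel, species_label: str, e_ancestry: float | None = None
) -> SpeciesPool:
    """Allele frequencies from the reference-flagged individuals of a species.

    Only individuals with ``reference_flag`` set contribute; missing allele
    copies are excluded per locus.
    """
    mask = panel.reference_flag & np.array(
        [s == species_label for s in panel.species_label]
    )
    if not mask.any():
        raise ValueError(f"no reference individuals labelled {species_label!r}")
    geno = panel.genotypes[mask]
    alleles, freqs = [], []
    for l in range(panel.n_loci):
        copies = geno[:, l, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            raise ValueError(
                f"locus {panel.locus_names[l]!r}: no typed reference copies"
            )
        vals, counts = np.unique(copies, return_counts=True)
        alleles.append(vals)
        freqs.append(counts / counts.sum())
    if e_ancestry is None:
        e_ancestry = 1.0 if species_label.lower().startswith("ie") else 0.0
    return SpeciesPool(species_label, alleles, freqs, e_ancestry)


def _gametes_from_pool(
    pool: SpeciesPool, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    L = pool.n_loci
    out = np.empty((n, L), dtype=np.int64)
    for l in range(L):
        out[:, l] = rng.choice(pool.alleles[l], size=n, p=pool.freqs[l])
    anc = np.full((n, L), pool.e_ancestry)
    return out, anc


def _gametes_from_panel(
    cross: CrossPanel, n: int, rng: np.random.Generator, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    geno = cross.panel.genotypes
    anc = cross.ancestry
    n_par, L, _ = geno.shape
    out = np.empty((n, L), dtype=np.int64)
    out_anc = np.empty((n, L))
    if mode == "individual_mendelian":
        pidx = rng.integers(0, n_par, size=n)
        copy = rng.integers(0, 2, size=(n, L))
        out = geno[pidx[:, None], np.arange(L)[None, :], copy]
        out_anc = anc[pidx[:, None], np.arange(L)[None, :], copy]
        # resolve transmitted missing copies from the other copy, then pool
        miss = out == MISSING
        if miss.any():
            other = geno[pidx[:, None], np.arange(L)[None, :], 1 - copy]
            other_anc = anc[pidx[:, None], np.arange(L)[None, :], 1 - copy]
            out = np.where(miss & (other != MISSING), other, out)
            out_anc = np.where(miss & (other != MISSING), other_anc, out_anc)
            _fill_from_pooled_copies(out, out_anc, geno, anc, rng)
    elif mode == "frequency_draw":
        for l in range(L):
            copies = geno[:, l, :].ravel()
            copy_anc = anc[:, l, :].ravel()
            ok = copies != MISSING
            pick = rng.integers(0, ok.sum(), size=n)
            out[:, l] = copies[ok][pick]
            out_anc[:, l] = copy_anc[ok][pick]
    else:
        raise ValueError(f"unknown transmission mode {mode!r}")
    return out, out_anc


def _fill_from_pooled_copies(out, out_anc, geno, anc, rng) -> None:
    """Replace still-missing transmitted copies with pooled panel copies."""
    for l in range(out.shape[1]):
        miss = out[:, l] == MISSING
        if not miss.any():
            continue
        copies = geno[:, l, :].ravel()
        copy_anc = anc[:, l, :].ravel()
        ok = copies != MISSING
        if not ok.any():
            raise ValueError(f"locus column {l}: no typed parental copies")
        pick = rng.integers(0, ok.sum(), size=int(miss.sum()))
        out[miss, l] = copies[ok][pick]
        out_anc[miss, l] = copy_anc[ok][pick]


def simulate_cross(
    class_name: str,
    parent_a,
    parent_b,
    n: int,
    seed: int | np.random.Generator = 0,
    mode: str = "individual_mendelian",
    locus_names: list[str] | None = None,
    id_prefix: str | None = None,
) -> CrossPanel:
    """Simulate ``n`` offspring of a cross class from two parental sources.

    Parents are :class:`SpeciesPool` frequency pools or previously simulated
    :class:`CrossPanel` objects (for serial classes).  Parent individuals
    are resampled with replacement.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _draw(parent):
        if isinstance(parent, SpeciesPool):
            return _gametes_from_pool(parent, n, rng)
        if isinstance(parent, CrossPanel):
            return _gametes_from_panel(parent, n, rng, mode)
        raise TypeError(f"unsupported parent material {type(parent).__name__}")

    g_a, a_a = _draw(parent_a)
    g_b, a_b = _draw(parent_b)
    geno = np.stack([g_a, g_b], axis=2)
    anc = np.stack([a_a, a_b], axis=2)
    L = geno.shape[1]
    loci = locus_names or [f"locus{i + 1}" for i in range(L)]
    prefix = id_prefix or class_name
    panel = GenotypePanel(
        individual_id=[f"{prefix}_{i + 1}" for i in range(n)],
        population=[class_name] * n,
        species_label=["hybrid"] * n,
        reference_flag=np.zeros(n, dtype=bool),
        genotypes=geno,
        locus_names=loci,
    )
    return CrossPanel(panel, [class_name] * n, anc)


def build_cross_panel(
    panel: GenotypePanel,
    per_class_n: int = 50,
    classes: tuple[str, ...] = TABLE_CLASS_SET,
    seed: int = 0,
    mode: str = "individual_mendelian",
    elegans_label: str = "Ie",
    graellsii_label: str = "Ig",
) -> CrossPanel:
    """Build the full artificial-hybrid panel (default: 7 classes x 50 = 350).

    Serial classes are generated recursively; a class needed only as a
    parent (e.g. 3EB when only 4EB is requested) is simulated but not
    included in the output.
    """
    rng = np.random.default_rng(seed)
    pool_e = estimate_pool(panel, elegans_label, e_ancestry=1.0)
    pool_g = estimate_pool(panel, graellsii_label, e_ancestry=0.0)
    materials: dict[str, object] = {"E": pool_e, "G": pool_g}

    def _ensure(name: str):
        if name in materials:
            return materials[name]
        pa, pb = CROSS_CLASSES[name]
        materials[name] = simulate_cross(
            name,
            _ensure(pa),
            _ensure(pb),
            per_class_n,
            rng,
            mode=mode,
            locus_names=panel.locus_names,
        )
        return materials[name]

    parts = [_ensure(c) for c in classes]
    merged = GenotypePanel.concatenate([p.panel for p in parts])
    labels = sum((p.class_label for p in parts), [])
    anc = np.concatenate([p.ancestry for p in parts])
    return CrossPanel(merged, labels, anc)
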