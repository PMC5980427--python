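"""Synthetic genotype panels and landscapes with the structure of a
two-species contact zone.

The genotype generator is a two-level drift model.  Ancestral multiallelic
frequencies are perturbed once per species with a Balding-Nichols-style
Dirichlet draw (concentration ``(1 - F) / F``), giving single-parameter
control of the between-species differentiation; population frequencies
drift from their species in the same way with a smaller ``F``.  Admixed
populations are composed of pedigree hybrid classes (F1 and serial
backcrosses) drawn from a per-population recipe.

The default study fixture mirrors a 14-population microsatellite survey of
*Ischnura elegans* and *I. graellsii*: 237 individuals at 12 loci, with 52
allopatric elegans plus 29 allopatric graellsii reference genotypes and
backcross-heavy recipes in the seven introgressed populations.

The landscape generator emits three mutually weakly correlated bioclimatic
surfaces (annual mean temperature, temperature annual range, annual
precipitation roles) on which Gaussian-response occurrence scenarios can
reproduce niche identity, displacement and background-driven regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cross_simulator import CROSS_CLASSES, gamete_e_probability
from .io_formats import EnvStack, GenotypePanel, OccurrenceSet, PopulationMetadata

__all__ = [
    "SpeciesFreqModel",
    "StudyDesign",
    "PopulationSpec",
    "NicheScenario",
    "DEFAULT_DIVERGENCE_F",
    "DEFAULT_WITHIN_SPECIES_F",
    "make_parental_frequencies",
    "drift_frequencies",
    "sample_population_genotypes",
    "make_admixed_population",
    "default_study_design",
    "default_study_fixture",
    "make_landscape",
    "make_occurrence_scenario",
]

#: species-level drift parameter calibrated so that two 30-sample species
#: panels at 12 default loci give a Weir-Cockerham theta near 0.25
#: (see scripts/calibrate_divergence.py for the calibration run)
DEFAULT_DIVERGENCE_F = 0.25

#: population-level drift within a species (keeps within-species theta low)
DEFAULT_WITHIN_SPECIES_F = 0.015


@dataclass
class SpeciesFreqModel:
    """Two-level Dirichlet drift model for microsatellite frequencies."""

    n_loci: int
    alleles_per_locus: list[int]
    ancestral_freqs: list[np.ndarray]
    allele_codes: list[np.ndarray]
    divergence_F: float = DEFAULT_DIVERGENCE_F
    within_species_F: float = DEFAULT_WITHIN_SPECIES_F

    def __post_init__(self) -> None:
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus length mismatch")
        if any(a < 2 for a in self.alleles_per_locus):
            raise ValueError("degenerate locus: fewer than 2 alleles")
        for f in self.ancestral_freqs:
            if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("ancestral frequencies must lie on the simplex")
        for F in (self.divergence_F, self.within_species_F):
            if not 0 < F < 1:
                raise ValueError("drift parameters must lie in (0, 1)")

    @classmethod
    def default(
        cls,
        n_loci: int = 12,
        seed: int = 0,
        divergence_F: float = DEFAULT_DIVERGENCE_F,
        within_species_F: float = DEFAULT_WITHIN_SPECIES_F,
        min_alleles: int = 4,
        max_alleles: int = 12,
    ) -> "SpeciesFreqModel":
        """Microsatellite-like model: 4-12 alleles per locus, broken-stick
        ancestral frequencies, allele codes spaced by repeat length."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(min_alleles, max_alleles + 1, size=n_loci).tolist()
        ancestral, codes = [], []
        for l, a in enumerate(counts):
            f = rng.dirichlet(np.full(a, 1.5))
            f = np.clip(f, 1e-4, None)
            ancestral.append(f / f.sum())
            base = 100 + 10 * l
            codes.append(base + 2 * np.arange(a))
        return cls(n_loci, counts, ancestral, codes, divergence_F, within_species_F)


def drift_frequencies(
    freqs: list[np.ndarray], F: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """One Dirichlet drift step with concentration ``(1 - F) / F``."""
    conc = (1.0 - F) / F
    out = []
    for f in freqs:
        g = rng.gamma(np.maximum(f * conc, 1e-6))
        g = np.clip(g, 1e-12, None)
        out.append(g / g.sum())
    return out


def make_parental_frequencies(
    model: SpeciesFreqModel, seed: int = 0
) -> dict[str, list[np.ndarray]]:
    """Draw per-species allele frequencies for the two parental species."""
    rng = np.random.default_rng(seed)
    return {
        "Ie": drift_frequencies(model.ancestral_freqs, model.divergence_F, rng),
        "Ig": drift_frequencies(model.ancestral_freqs, model.divergence_F, rng),
    }


def _freq_pairs(model: SpeciesFreqModel, freqs: list[np.ndarray]):
    return list(zip(model.allele_codes, freqs))


def sample_population_genotypes(
    freqs,
    n: int,
    seed: int | np.random.Generator = 0,
    population: str = "pop",
    species_label: str = "unknown",
    reference: bool = False,
    locus_names: list[str] | None = None,
    id_prefix: str | None = None,
) -> GenotypePanel:
    """Hardy-Weinberg sampling: each allele copy i.i.d. from the population
    frequencies, loci independent (linkage equilibrium).

    ``freqs`` is a list of ``(allele_codes, probabilities)`` pairs per locus.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(freqs)
    geno = np.empty((n, L, 2), dtype=np.int64)
    for l, (codes, p) in enumerate(freqs):
        geno[:, l, :] = rng.choice(codes, size=(n, 2), p=np.asarray(p))
    prefix = id_prefix or population
    return GenotypePanel(
        individual_id=[f"{prefix}_{i + 1}" for i in range(n)],
        population=[population] * n,
        species_label=[species_label] * n,
        reference_flag=np.full(n, reference),
        genotypes=geno,
        locus_names=locus_names or [f"locus{i + 1}" for i in range(L)],
    )


def make_admixed_population(
    recipe: dict[str, float],
    parental_freqs: dict[str, list],
    n: int,
    seed: int | np.random.Generator = 0,
    population: str = "pop",
    species_label: str = "Ie",
    locus_names: list[str] | None = None,
) -> tuple[GenotypePanel, list[str], np.ndarray]:
    """Sample a population whose individuals are a mixture of cross classes.

    ``recipe`` maps class names (``pureE``, ``pureG``, ``F1``, ``1EB``, ...)
    to proportions summing to 1.  ``parental_freqs`` holds the two parental
    ``(codes, probs)`` frequency lists under keys ``"E"`` and ``"G"``.

    With unlinked loci, each allele copy of a class-C individual descends
    from the elegans pool independently with the gamete lineage probability
    of C's corresponding parent, so genotypes are generated by per-copy
    lineage coin flips followed by allele draws from the matching pool.

    Returns the panel fragment, the class label per individual, and the
    tracked per-copy elegans-lineage array of shape ``(n, n_loci, 2)``.
    """
    if abs(sum(recipe.values()) - 1.0) > 1e-9:
        raise ValueError("recipe proportions must sum to 1")
    for cls in recipe:
        if cls not in ("pureE", "pureG") and cls not in CROSS_CLASSES:
            raise ValueError(f"unknown cross class {cls!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq_e, freq_g = parental_freqs["E"], parental_freqs["G"]
    L = len(freq_e)

    names = list(recipe)
    probs = np.array([recipe[c] for c in names])
    classes = [names[i] for i in rng.choice(len(names), size=n, p=probs)]

    # per-copy elegans-lineage probability, one gamete per parent
    gam = {
        "pureE": (1.0, 1.0),
        "pureG": (0.0, 0.0),
        **{
            c: (gamete_e_probability(pa), gamete_e_probability(pb))
            for c, (pa, pb) in CROSS_CLASSES.items()
        },
    }
    p_copy = np.array([gam[c] for c in classes])  # (n, 2)
    lineage = rng.random((n, L, 2)) < p_copy[:, None, :]

    geno = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        codes_e, pe = freq_e[l]
        codes_g, pg = freq_g[l]
        draws_e = rng.choice(codes_e, size=(n, 2), p=np.asarray(pe))
        draws_g = rng.choice(codes_g, size=(n, 2), p=np.asarray(pg))
        geno[:, l, :] = np.where(lineage[:, l, :], draws_e, draws_g)

    panel = GenotypePanel(
        individual_id=[f"{population}_{i + 1}" for i in range(n)],
        population=[population] * n,
        species_label=[species_label] * n,
        reference_flag=np.zeros(n, dtype=bool),
        genotypes=geno,
        locus_names=locus_names or [f"locus{i + 1}" for i in range(L)],
    )
    return panel, classes, lineage.astype(float)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    name: str
    species_label: str
    ecology: str
    n_individuals: int
    admixture_recipe: dict[str, float]
    latitude: float
    longitude: float
    year: int = 2008
    reference: bool = False

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if abs(sum(self.admixture_recipe.values()) - 1.0) > 1e-9:
            raise ValueError("recipe proportions must sum to 1")


@dataclass
class StudyDesign:
    populations: list[PopulationSpec]
    n_loci: int = 12

    @property
    def total_individuals(self) -> int:
        return sum(p.n_individuals for p in self.populations)


#: backcross-heavy recipe for introgressed populations: most individuals sit
#: in first/second elegans backcross classes, exercising the intermediate
#: admixture bands
_SYMPATRIC_RECIPE = {
    "1EB": 0.45,
    "F1": 0.25,
    "2EB": 0.15,
    "1GB": 0.08,
    "3EB": 0.04,
    "pureE": 0.03,
}
_PARAPATRIC_MILD = {"pureE": 0.75, "3EB": 0.15, "2EB": 0.10}
_PARAPATRIC_MIXED = {"pureE": 0.30, "1EB": 0.20, "2EB": 0.25, "F1": 0.15, "1GB": 0.10}
_PURE_E = {"pureE": 1.0}
_PURE_G = {"pureG": 1.0}


def default_study_design() -> StudyDesign:
    """14-population design: 237 individuals, 81 of them reference."""
    rows = [
        # name, species, ecology, N, recipe, lat, lon, year, reference
        ("Kaiserslautern", "Ie", "allopatric", 18, _PURE_E, 49.44, 7.77, 2009, True),
        ("GranSasso", "Ie", "allopatric", 19, _PURE_E, 42.45, 13.66, 2008, True),
        ("Liverpool", "Ie", "allopatric", 15, _PURE_E, 53.41, -2.98, 2008, True),
        ("Cordoba", "Ig", "allopatric", 13, _PURE_G, 37.89, -4.78, 2008, True),
        ("RibeiraDeCobres", "Ig", "allopatric", 16, _PURE_G, 37.60, -7.90, 2008, True),
        ("Vigueirat", "Ie", "parapatric", 16, _PARAPATRIC_MILD, 43.53, 4.75, 2008, False),
        ("Menorca", "Ie", "parapatric", 8, _PARAPATRIC_MIXED, 39.95, 4.05, 2008, False),
        ("Doninos", "Ie", "sympatric_introgressed", 20, _SYMPATRIC_RECIPE, 43.49, -8.29, 2007, False),
        ("Arreo", "Ie", "sympatric_introgressed", 17, _SYMPATRIC_RECIPE, 42.77, -2.99, 2008, False),
        ("Baldajo", "Ie", "sympatric_introgressed", 19, _SYMPATRIC_RECIPE, 43.37, -3.51, 2008, False),
        ("Alfaro", "Ie", "sympatric_introgressed", 20, _SYMPATRIC_RECIPE, 42.18, -1.75, 2008, False),
        ("Europa", "Ie", "sympatric_introgressed", 18, _SYMPATRIC_RECIPE, 42.41, 1.93, 2008, False),
        ("Amposta", "Ie", "sympatric_introgressed", 20, _SYMPATRIC_RECIPE, 40.71, 0.58, 2008, False),
        ("MarjalDelMoro", "Ie", "sympatric_introgressed", 18, _SYMPATRIC_RECIPE, 39.63, -0.26, 2008, False),
    ]
    pops = [
        PopulationSpec(n, sp, eco, N, rec, lat, lon, yr, ref)
        for n, sp, eco, N, rec, lat, lon, yr, ref in rows
    ]
    return StudyDesign(pops, n_loci=12)


def default_study_fixture(
    seed: int = 0,
    design: StudyDesign | None = None,
    model: SpeciesFreqModel | None = None,
    return_truth: bool = False,
):
    """Simulate the full study panel.

    Reference flags are set exactly for allopatric graellsii and allopatric
    (non-hybrid-zone) elegans individuals.  With ``return_truth`` also
    returns per-individual class labels and tracked elegans ancestry.
    """
    rng = np.random.default_rng(seed)
    design = design or default_study_design()
    model = model or SpeciesFreqModel.default(n_loci=design.n_loci, seed=seed)
    species_freqs = make_parental_frequencies(model, seed=rng.integers(2**31))
    locus_names = [f"I-{100 + 3 * i:03d}" for i in range(model.n_loci)]

    parts, metas, labels, ancestry = [], [], [], []
    for spec in design.populations:
        # population-level drift for each parental gene pool
        pop_e = _freq_pairs(
            model, drift_frequencies(species_freqs["Ie"], model.within_species_F, rng)
        )
        pop_g = _freq_pairs(
            model, drift_frequencies(species_freqs["Ig"], model.within_species_F, rng)
        )
        panel, cls, anc = make_admixed_population(
            spec.admixture_recipe,
            {"E": pop_e, "G": pop_g},
            spec.n_individuals,
            rng,
            population=spec.name,
            species_label=spec.species_label,
            locus_names=locus_names,
        )
        panel.reference_flag[:] = spec.reference
        parts.append(panel)
        labels.extend(cls)
        ancestry.append(anc)
        metas.append(
            PopulationMetadata(
                population=spec.name,
                species_label=spec.species_label,
                ecology=spec.ecology,
                latitude=spec.latitude,
                longitude=spec.longitude,
                year=spec.year,
            )
        )
    panel = GenotypePanel.concatenate(parts)
    if return_truth:
        return panel, metas, labels, np.concatenate(ancestry).mean(axis=(1, 2))
    return panel, metas


# ---------------------------------------------------------------------------
# landscapes and occurrence scenarios
# ---------------------------------------------------------------------------


def make_landscape(
    n_rows: int = 120, n_cols: int = 160, seed: int = 0, cell_size: float = 1.0
) -> EnvStack:
    """Three-variable synthetic landscape (1-km-style grid).

    ``bio_1`` (annual mean temperature) rises southward, ``bio_7``
    (temperature annual range) rises eastward, and ``bio_12`` (annual
    precipitation) is smoothed spatial noise; pairwise correlations stay
    below the 0.7 pruning threshold by construction.
    """
    if n_rows < 20 or n_cols < 20:
        raise ValueError("landscape must be at least 20 x 20 cells")
    rng = np.random.default_rng(seed)
    rows = np.linspace(0, 1, n_rows)[:, None]
    cols = np.linspace(0, 1, n_cols)[None, :]
    noise = lambda s: ndimage.gaussian_filter(rng.standard_normal((n_rows, n_cols)), s)

    bio_1 = 5.0 + 13.0 * rows + 1.2 * noise(3)  # degC, warmer south (larger row)
    bio_7 = 20.0 + 15.0 * cols + 1.5 * noise(3)  # degC, more continental east
    pr = noise(6)
    bio_12 = 700.0 + 350.0 * (pr - pr.mean()) / max(pr.std(), 1e-9)  # mm

    return EnvStack(
        variables={
            "bio_1": bio_1 + 0 * rows,
            "bio_7": bio_7 + 0 * cols,
            "bio_12": bio_12,
        },
        cell_size=cell_size,
        origin_x=0.0,
        origin_y=0.0,
        nodata_value=-9999.0,
    )


@dataclass
class GroupResponse:
    """Gaussian niche response of one group on each landscape variable."""

    optimum: dict[str, float]
    breadth: dict[str, float]
    region: tuple[float, float, float, float] | None = None  # x0, x1, y0, y1
    n_points: int = 300

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.breadth.values()):
            raise ValueError("breadths must be positive")
        for v in self.optimum.values():
            if not np.isfinite(v):
                raise ValueError("optima must be finite")


@dataclass
class NicheScenario:
    """Named set of group responses on one landscape."""

    tag: str  # identical | displaced | background_driven
    groups: dict[str, GroupResponse] = field(default_factory=dict)

    @classmethod
    def preset(
        cls, tag: str, stack: EnvStack, n_points: tuple[int, int] = (712, 649)
    ) -> "NicheScenario":
        """Two-group scenarios spanning the qualitative study regimes.

        ``identical``: both groups share one optimum and the full extent.
        ``displaced``: optima 4 climatic SD apart on ``bio_1``.
        ``background_driven``: identical responses but disjoint available
        regions, so occupied climates differ only through the background.
        """
        v = {n: stack.variables[n][~stack.nodata_mask] for n in stack.variables}
        mid = {n: float(np.mean(x)) for n, x in v.items()}
        sd = {n: float(np.std(x)) for n, x in v.items()}
        breadth = {n: 1.0 * sd[n] for n in sd}
        wide = {n: 3.0 * sd[n] for n in sd}
        x1 = stack.origin_x + stack.n_cols * stack.cell_size
        y1 = stack.origin_y + stack.n_rows * stack.cell_size
        full = (stack.origin_x, x1, stack.origin_y, y1)
        north = (stack.origin_x, x1, stack.origin_y + 0.55 * (y1 - stack.origin_y), y1)
        south = (stack.origin_x, x1, stack.origin_y, stack.origin_y + 0.45 * (y1 - stack.origin_y))
        na, nb = n_points
        if tag == "identical":
            groups = {
                "group_a": GroupResponse(dict(mid), dict(breadth), full, na),
                "group_b": GroupResponse(dict(mid), dict(breadth), full, nb),
            }
        elif tag == "displaced":
            opt_a = dict(mid)
            opt_b = dict(mid)
            opt_a["bio_1"] = mid["bio_1"] - 2.0 * sd["bio_1"]
            opt_b["bio_1"] = mid["bio_1"] + 2.0 * sd["bio_1"]
            groups = {
                "group_a": GroupResponse(opt_a, dict(breadth), full, na),
                "group_b": GroupResponse(opt_b, dict(breadth), full, nb),
            }
        elif tag == "background_driven":
            groups = {
                "group_a": GroupResponse(dict(mid), dict(wide), north, na),
                "group_b": GroupResponse(dict(mid), dict(wide), south, nb),
            }
        else:
            raise ValueError(f"unknown scenario tag {tag!r}")
        return cls(tag, groups)


def make_occurrence_scenario(
    stack: EnvStack, scenario: NicheScenario, seed: int = 0
) -> dict[str, OccurrenceSet]:
    """Sample occurrence points per group, cells weighted by the product of
    Gaussian responses and restricted to the group's background region."""
    rng = np.random.default_rng(seed)
    out: dict[str, OccurrenceSet] = {}
    for name, grp in scenario.groups.items():
        cells = stack.valid_cells()
        centers = np.array([stack.cell_center(r, c) for r, c in cells])
        if grp.region is not None:
            x0, x1, y0, y1 = grp.region
            keep = (
                (centers[:, 0] >= x0)
                & (centers[:, 0] <= x1)
                & (centers[:, 1] >= y0)
                & (centers[:, 1] <= y1)
            )
            cells, centers = cells[keep], centers[keep]
        if len(cells) == 0:
            raise ValueError(f"group {name!r}: empty background region")
        logw = np.zeros(len(cells))
        for var, opt in grp.optimum.items():
            vals = stack.variables[var][cells[:, 0], cells[:, 1]]
            logw -= 0.5 * ((vals - opt) / grp.breadth[var]) ** 2
        w = np.exp(logw - logw.max())
        if w.sum() <= 0 or not np.isfinite(w.sum()):
            raise ValueError(f"group {name!r}: all-zero suitability")
        pick = rng.choice(len(cells), size=grp.n_points, p=w / w.sum())
        out[name] = OccurrenceSet(group=name, points=centers[pick])
    return out
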