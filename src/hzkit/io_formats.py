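"""Readers and writers for the text formats the toolkit consumes.

Genotype panels travel as Genepop (2- or 3-digit diploid) or STRUCTURE
matrix files, environmental variables as ESRI ASCII grids, and occurrence
records as ``group,x,y`` CSV.  All parsers are strict: malformed input
raises :class:`FormatError` rather than being silently truncated.

Missing genotypes are unified internally to the single sentinel ``0``
regardless of the source dialect (Genepop ``000`` vs STRUCTURE ``-9``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: internal missing-allele sentinel (Genepop "000", STRUCTURE "-9" map here)
MISSING = 0

__all__ = [
    "MISSING",
    "FormatError",
    "GenotypePanel",
    "PopulationMetadata",
    "EnvStack",
    "OccurrenceSet",
    "read_genepop",
    "write_genepop",
    "read_structure_matrix",
    "write_structure_matrix",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class GenotypePanel:
    """Diploid multilocus genotypes for a set of individuals.

    Parameters
    ----------
    individual_id
        One identifier per individual.
    population
        Population name per individual.
    species_label
        Species tag per individual (e.g. ``"Ie"``, ``"Ig"``, ``"unknown"``).
        Each population must carry exactly one species label.
    reference_flag
        True for individuals usable to seed a cluster in supervised
        admixture (the "population flag" semantics).
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)``; positive
        entries are allele codes (microsatellite sizes in bp), ``0`` is
        missing.
    locus_names
        One name per locus.
    """

    individual_id: list[str]
    population: list[str]
    species_label: list[str]
    reference_flag: np.ndarray
    genotypes: np.ndarray
    locus_names: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.reference_flag = np.asarray(self.reference_flag, dtype=bool)
        n = len(self.individual_id)
        if n == 0 or len(self.locus_names) == 0:
            raise ValueError("panel needs at least one individual and one locus")
        if self.genotypes.shape != (n, len(self.locus_names), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n} individuals x {len(self.locus_names)} loci x 2"
            )
        if len(self.population) != n or len(self.species_label) != n:
            raise ValueError("per-individual metadata length mismatch")
        if (self.genotypes < 0).any():
            raise ValueError("negative allele codes; missing must be 0")
        pop2sp: dict[str, str] = {}
        for pop, sp in zip(self.population, self.species_label):
            if pop2sp.setdefault(pop, sp) != sp:
                raise ValueError(f"population {pop!r} maps to several species labels")

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Population names in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p)
        return list(seen)

    def population_species(self) -> dict[str, str]:
        return dict(zip(self.population, self.species_label))

    def subset(self, mask: np.ndarray) -> "GenotypePanel":
        """Panel restricted to a boolean mask or integer index array
        (indices preserve the given order)."""
        arr = np.asarray(mask)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return GenotypePanel(
            [self.individual_id[i] for i in idx],
            [self.population[i] for i in idx],
            [self.species_label[i] for i in idx],
            self.reference_flag[idx],
            self.genotypes[idx],
            list(self.locus_names),
        )

    def select_populations(self, pops) -> "GenotypePanel":
        keep = set(pops)
        return self.subset(np.array([p in keep for p in self.population]))

    @staticmethod
    def concatenate(panels: list["GenotypePanel"]) -> "GenotypePanel":
        if not panels:
            raise ValueError("nothing to concatenate")
        loci = panels[0].locus_names
        for p in panels[1:]:
            if p.locus_names != loci:
                raise ValueError("locus names differ between panels")
        return GenotypePanel(
            sum((p.individual_id for p in panels), []),
            sum((p.population for p in panels), []),
            sum((p.species_label for p in panels), []),
            np.concatenate([p.reference_flag for p in panels]),
            np.concatenate([p.genotypes for p in panels]),
            list(loci),
        )


@dataclass
class PopulationMetadata:
    """Sampling metadata for one population."""

    population: str
    species_label: str
    ecology: str  # allopatric | parapatric | sympatric_introgressed
    latitude: float
    longitude: float
    year: int = 0

    ECOLOGY_CLASSES = ("allopatric", "parapatric", "sympatric_introgressed")

    def __post_init__(self) -> None:
        if self.ecology not in self.ECOLOGY_CLASSES:
            raise ValueError(f"unknown ecology class {self.ecology!r}")
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError("coordinates out of range")


@dataclass
class EnvStack:
    """A set of co-registered 2-D environmental grids.

    All variables share shape, origin (lower-left corner), cell size and
    nodata mask.  Row 0 is the northernmost row.
    """

    variables: dict[str, np.ndarray]
    cell_size: float
    origin_x: float
    origin_y: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.variables.values()}
        if len(shapes) != 1:
            raise ValueError("all variable grids must share one shape")
        masks = [self.mask_of(name) for name in self.variables]
        for m in masks[1:]:
            if not np.array_equal(m, masks[0]):
                raise ValueError("variables disagree on the nodata mask")
        for name, grid in self.variables.items():
            valid = grid[~self.mask_of(name)]
            if valid.size and not np.isfinite(valid).all():
                raise ValueError(f"non-finite values in variable {name!r}")

    @property
    def n_rows(self) -> int:
        return next(iter(self.variables.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.variables.values())).shape[1]

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    def mask_of(self, name: str) -> np.ndarray:
        g = self.variables[name]
        return (g == self.nodata_value) | ~np.isfinite(g)

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where cells carry no data."""
        return self.mask_of(next(iter(self.variables)))

    def valid_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of data cells."""
        return np.argwhere(~self.nodata_mask)

    # -- coordinate mapping -------------------------------------------------

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a planar point to its (row, col) cell, half-open intervals.

        Returns None outside the extent.  A point exactly on the upper x/y
        edge belongs to the last column/top row (closed upper boundary for
        the outermost cells so edge points are retained).
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin_y) / self.cell_size))
        if x == self.origin_x + self.n_cols * self.cell_size:
            col = self.n_cols - 1
        if y == self.origin_y + self.n_rows * self.cell_size:
            row_from_bottom = self.n_rows - 1
        if not (0 <= col < self.n_cols and 0 <= row_from_bottom < self.n_rows):
            return None
        return self.n_rows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def select(self, names) -> "EnvStack":
        return replace(self, variables={n: self.variables[n] for n in names})

    def features_at(self, cells: np.ndarray) -> np.ndarray:
        """Raw variable values at (row, col) cells; shape (k, n_variables)."""
        cells = np.asarray(cells)
        return np.column_stack(
            [self.variables[n][cells[:, 0], cells[:, 1]] for n in self.variables]
        )


@dataclass
class OccurrenceSet:
    """Presence points for one group (species x region class)."""

    group: str
    points: np.ndarray  # (n, 2) of (x, y)
    n_dropped: int = 0
    duplicate_cells: int = field(default=0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def cells(self, stack: EnvStack) -> np.ndarray:
        """Unique (row, col) cells occupied by the points."""
        idx = [stack.point_to_cell(x, y) for x, y in self.points]
        idx = [c for c in idx if c is not None]
        return np.unique(np.asarray(idx, dtype=int).reshape(-1, 2), axis=0)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------


def _split_genepop_individual(line: str, lineno: int) -> tuple[str, list[str]]:
    if "," not in line:
        raise FormatError(f"line {lineno}: individual line lacks ',' separator")
    ident, _, rest = line.partition(",")
    return ident.strip(), rest.split()


def read_genepop(path: str) -> GenotypePanel:
    """Read a Genepop file (2- or 3-digit dialect, auto-detected).

    The dialect is detected from the genotype token width, which must be
    uniform across the file (4 characters = 2-digit alleles, 6 = 3-digit).
    Missing alleles (``00``/``000``) map to the internal sentinel 0.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if len(lines) < 4:
        raise FormatError("file too short for Genepop")
    lines = lines[1:]  # title

    locus_names: list[str] = []
    body_start = None
    for k, (lineno, ln) in enumerate(lines):
        if ln.strip().upper() == "POP":
            body_start = k
            break
        locus_names.extend(s.strip() for s in ln.split(",") if s.strip())
    if body_start is None:
        raise FormatError("no POP separator found")
    if not locus_names:
        raise FormatError("no locus names before first POP")

    pops: list[list[tuple[str, list[str]]]] = []
    for lineno, ln in lines[body_start:]:
        if ln.strip().upper() == "POP":
            pops.append([])
            continue
        pops[-1].append((*_split_genepop_individual(ln, lineno), lineno)[:2])
    widths = {
        len(tok) for pop in pops for _, toks in pop for tok in toks
    }
    if widths - {4, 6}:
        raise FormatError(f"unknown genotype token widths {sorted(widths - {4, 6})}")
    if len(widths) != 1:
        raise FormatError(f"mixed 2- and 3-digit tokens in one file: {sorted(widths)}")
    half = widths.pop() // 2

    ids, popnames, genos = [], [], []
    for p, pop in enumerate(pops):
        name = pop[0][0] if pop else f"pop{p + 1}"
        for ident, toks in pop:
            if len(toks) != len(locus_names):
                raise FormatError(
                    f"individual {ident!r}: {len(toks)} genotypes for "
                    f"{len(locus_names)} loci"
                )
            try:
                g = [(int(t[:half]), int(t[half:])) for t in toks]
            except ValueError as exc:
                raise FormatError(f"individual {ident!r}: bad token ({exc})") from None
            ids.append(ident)
            popnames.append(name)
            genos.append(g)
    return GenotypePanel(
        individual_id=ids,
        population=popnames,
        species_label=["unknown"] * len(ids),
        reference_flag=np.zeros(len(ids), dtype=bool),
        genotypes=np.asarray(genos),
        locus_names=locus_names,
    )


def write_genepop(panel: GenotypePanel, path: str, title: str = "hzkit export") -> None:
    """Write the 3-digit Genepop dialect; missing alleles become ``000``."""
    if panel.genotypes.max(initial=0) >= 1000:
        raise ValueError("allele codes >= 1000 are not representable in Genepop")
    order = {p: i for i, p in enumerate(panel.populations)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in panel.locus_names:
            fh.write(name + "\n")
        for pop in panel.populations:
            fh.write("Pop\n")
            for i in range(panel.n_individuals):
                if panel.population[i] != pop:
                    continue
                toks = [
                    f"{a:03d}{b:03d}" for a, b in panel.genotypes[i]
                ]
                fh.write(f"{panel.individual_id[i]} , " + " ".join(toks) + "\n")
    del order


# ---------------------------------------------------------------------------
# STRUCTURE matrix
# ---------------------------------------------------------------------------


def read_structure_matrix(
    path: str,
    one_row_per_individual: bool = True,
    population_names: dict[str, str] | None = None,
    species_of_population: dict[str, str] | None = None,
) -> GenotypePanel:
    """Read a STRUCTURE input matrix.

    Columns: id, popID, popflag, then loci.  One-row layout carries two
    allele columns per locus; two-row layout one column per locus with two
    consecutive rows per individual.  ``-9`` (or 0) marks missing data.
    An optional header line of locus names is honoured when present.
    """
    with open(path) as fh:
        rows = [ln.split() for ln in fh if ln.strip()]
    if not rows:
        raise FormatError("empty STRUCTURE file")

    def _is_data(row: list[str]) -> bool:
        return len(row) >= 4 and all(_intlike(t) for t in row[1:])

    if _is_data(rows[0]):
        n_fields = len(rows[0]) - 3
        if one_row_per_individual:
            if n_fields % 2:
                raise FormatError("odd allele-column count in one-row layout")
            locus_names = [f"locus{i + 1}" for i in range(n_fields // 2)]
        else:
            locus_names = [f"locus{i + 1}" for i in range(n_fields)]
    else:
        locus_names = rows[0]
        rows = rows[1:]

    ids, pops, flags, genos = [], [], [], []
    if one_row_per_individual:
        for row in rows:
            ident, pop, flag, alleles = row[0], row[1], int(row[2]), row[3:]
            if len(alleles) != 2 * len(locus_names):
                raise FormatError(f"individual {ident!r}: ragged allele count")
            g = np.array([int(a) for a in alleles], dtype=np.int64).reshape(-1, 2)
            ids.append(ident)
            pops.append(pop)
            flags.append(bool(flag))
            genos.append(g)
    else:
        if len(rows) % 2:
            raise FormatError("two-row layout needs an even number of data rows")
        for r1, r2 in zip(rows[::2], rows[1::2]):
            if r1[0] != r2[0]:
                raise FormatError(f"row pair mismatch: {r1[0]!r} vs {r2[0]!r}")
            if len(r1) != len(r2) or len(r1) - 3 != len(locus_names):
                raise FormatError(f"individual {r1[0]!r}: ragged allele count")
            ids.append(r1[0])
            pops.append(r1[1])
            flags.append(bool(int(r1[2])))
            genos.append(
                np.array(
                    [[int(a), int(b)] for a, b in zip(r1[3:], r2[3:])], dtype=np.int64
                )
            )
    geno = np.stack(genos)
    geno[geno == -9] = MISSING
    if (geno < 0).any():
        raise FormatError("negative allele codes other than the -9 sentinel")
    if population_names:
        pops = [population_names.get(p, p) for p in pops]
    species = [
        (species_of_population or {}).get(p, "unknown") for p in pops
    ]
    return GenotypePanel(ids, pops, species, np.array(flags), geno, locus_names)


def _intlike(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def write_structure_matrix(
    panel: GenotypePanel,
    path: str,
    population_codes: dict[str, int] | None = None,
    header: bool = True,
) -> None:
    """Write the one-row-per-individual STRUCTURE layout (missing = -9)."""
    codes = population_codes or {p: i + 1 for i, p in enumerate(panel.populations)}
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(panel.locus_names) + "\n")
        for i in range(panel.n_individuals):
            g = panel.genotypes[i].ravel().astype(int)
            g = np.where(g == MISSING, -9, g)
            fh.write(
                f"{panel.individual_id[i]} {codes[panel.population[i]]} "
                f"{int(panel.reference_flag[i])} " + " ".join(map(str, g)) + "\n"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str, name: str = "var") -> EnvStack:
    """Read one ESRI ASCII grid into a single-variable :class:`EnvStack`."""
    with open(path) as fh:
        tokens: dict[str, float] = {}
        header_lines = 0
        body: list[str] = []
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if parts[0].lower() in _HEADER_KEYS + ("nodata_value",) and len(parts) == 2:
                tokens[parts[0].lower()] = float(parts[1])
                header_lines += 1
            else:
                body.append(ln)
    for key in _HEADER_KEYS:
        if key not in tokens:
            raise FormatError(f"missing header key {key!r}")
    nrows, ncols = int(tokens["nrows"]), int(tokens["ncols"])
    nodata = tokens.get("nodata_value", -9999.0)
    try:
        values = np.array(" ".join(body).split(), dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric grid body: {exc}") from None
    if values.size != nrows * ncols:
        raise FormatError(
            f"grid body has {values.size} values, expected {nrows * ncols}"
        )
    grid = values.reshape(nrows, ncols)  # row 0 is already northernmost
    return EnvStack(
        variables={name: grid},
        cell_size=tokens["cellsize"],
        origin_x=tokens["xllcorner"],
        origin_y=tokens["yllcorner"],
        nodata_value=nodata,
    )


def write_ascii_grid(stack: EnvStack, name: str, path: str, fmt: str = "%.6g") -> None:
    grid = stack.variables[name]
    with open(path, "w") as fh:
        fh.write(f"ncols {stack.n_cols}\n")
        fh.write(f"nrows {stack.n_rows}\n")
        fh.write(f"xllcorner {stack.origin_x:.10g}\n")
        fh.write(f"yllcorner {stack.origin_y:.10g}\n")
        fh.write(f"cellsize {stack.cell_size:.10g}\n")
        fh.write(f"NODATA_value {stack.nodata_value:.10g}\n")
        np.savetxt(fh, grid, fmt=fmt)


def read_env_stack(paths: dict[str, str]) -> EnvStack:
    """Read several ASCII grids into one co-registered stack."""
    stacks = {name: read_ascii_grid(p, name) for name, p in paths.items()}
    first = next(iter(stacks.values()))
    merged = dict(first.variables)
    for name, st in stacks.items():
        if (st.n_rows, st.n_cols, st.cell_size, st.origin_x, st.origin_y) != (
            first.n_rows,
            first.n_cols,
            first.cell_size,
            first.origin_x,
            first.origin_y,
        ):
            raise FormatError(f"grid {name!r} is not co-registered with the others")
        merged[name] = st.variables[name]
    return replace(first, variables=merged)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def read_occurrences(path: str, stack: EnvStack) -> dict[str, OccurrenceSet]:
    """Read a ``group,x,y`` CSV, dropping points off-grid or on nodata cells.

    Returns one :class:`OccurrenceSet` per group, in order of first
    appearance; the number of dropped points is recorded per set and logged.
    """
    df = pd.read_csv(path)
    missing = {"group", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"occurrence CSV lacks columns {sorted(missing)}")
    mask = stack.nodata_mask
    out: dict[str, OccurrenceSet] = {}
    for group, sub in df.groupby("group", sort=False):
        kept, dropped = [], 0
        cells_seen: set[tuple[int, int]] = set()
        dupes = 0
        for x, y in zip(sub["x"], sub["y"]):
            cell = stack.point_to_cell(float(x), float(y))
            if cell is None or mask[cell]:
                dropped += 1
                continue
            if cell in cells_seen:
                dupes += 1
            cells_seen.add(cell)
            kept.append((float(x), float(y)))
        if dropped:
            logger.info("group %s: dropped %d off-grid/nodata points", group, dropped)
        out[str(group)] = OccurrenceSet(
            group=str(group),
            points=np.asarray(kept, dtype=float).reshape(-1, 2),
            n_dropped=dropped,
            duplicate_cells=dupes,
        )
    return out


def write_occurrences(sets, path: str) -> None:
    if isinstance(sets, dict):
        sets = list(sets.values())
    rows = [
        {"group": s.group, "x": x, "y": y} for s in sets for x, y in s.points
    ]
    pd.DataFrame(rows, columns=["group", "x", "y"]).to_csv(path, index=False)


def write_population_metadata(meta: list[PopulationMetadata], path: str) -> None:
    pd.DataFrame(
        [
            {
                "population": m.population,
                "species_label": m.species_label,
                "ecology": m.ecology,
                "latitude": m.latitude,
                "longitude": m.longitude,
                "year": m.year,
            }
            for m in meta
        ]
    ).to_csv(path, index=False)


def read_population_metadata(path: str) -> list[PopulationMetadata]:
    df = pd.read_csv(path)
    return [
        PopulationMetadata(
            population=str(r.population),
            species_label=str(r.species_label),
            ecology=str(r.ecology),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
            year=int(getattr(r, "year", 0) or 0),
        )
        for r in df.itertuples()
    ]
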