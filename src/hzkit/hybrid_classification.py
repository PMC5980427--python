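"""Hybrid-category tables and class assignment from admixture output.

Admixture proportions are summarised two ways: per-population counts in
the standard integer-percent bins (>=75, 74-56, 55-50, 49-26, <=25), and
individual assignment to conservative hybrid groups whose boundaries come
from the Q1 ranges of simulated cross classes (F1, serial backcrosses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .admixture import AdmixtureResult

__all__ = [
    "DEFAULT_BINS",
    "AssignmentBins",
    "ClassRangeTable",
    "bin_q_values",
    "derive_class_ranges",
    "conservative_groups",
    "classify_by_class_ranges",
]


@dataclass(frozen=True)
class AssignmentBins:
    """Ordered inclusive integer-percent bins partitioning 0-100."""

    edges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        covered = sorted((lo, hi) for _, lo, hi in self.edges)
        pos = 0
        for lo, hi in covered:
            if lo != pos or hi < lo:
                raise ValueError("bins must tile 0-100 without gaps or overlap")
            pos = hi + 1
        if pos != 101:
            raise ValueError("bins must end at 100")

    def label_for(self, q: float) -> str:
        """Integer-percent rounding then inclusive bin lookup."""
        pct = int(np.floor(100.0 * q + 0.5))
        for label, lo, hi in self.edges:
            if lo <= pct <= hi:
                return label
        raise ValueError(f"percent {pct} outside 0-100")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.edges]


DEFAULT_BINS = AssignmentBins(
    (
        (">=75", 75, 100),
        ("74-56", 56, 74),
        ("55-50", 50, 55),
        ("49-26", 26, 49),
        ("<=25", 0, 25),
    )
)


def bin_q_values(
    result: AdmixtureResult, bins: AssignmentBins = DEFAULT_BINS
) -> pd.DataFrame:
    """Per-population counts of individuals per admixture-proportion bin."""
    labels = [bins.label_for(q) for q in result.q1]
    df = pd.DataFrame({"population": result.population, "bin": labels})
    table = (
        df.groupby(["population", "bin"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=bins.labels, fill_value=0)
    )
    # keep input population order
    order = list(dict.fromkeys(result.population))
    return table.reindex(order)


@dataclass
class ClassRangeTable:
    """Observed Q1 ranges of simulated cross classes.

    ``lo``/``hi`` are the configurable quantile bounds (default 2.5/97.5%),
    ``q_min``/``q_max`` the raw extremes.
    """

    table: pd.DataFrame  # index class; columns n, q_min, q_max, lo, hi, mean
    quantiles: tuple[float, float]
    samples: dict[str, np.ndarray]

    def range_of(self, cls: str) -> tuple[float, float]:
        row = self.table.loc[cls]
        return float(row["lo"]), float(row["hi"])


def derive_class_ranges(
    cross_result: AdmixtureResult,
    class_labels: list[str],
    quantiles: tuple[float, float] = (0.025, 0.975),
    min_class_n: int = 5,
) -> ClassRangeTable:
    """Per-class Q1 ranges from an admixture run on a simulated cross panel.

    Quantile bounds are used instead of raw extremes because extremes grow
    with class sample size; classes with fewer than ``min_class_n``
    members are flagged with a warning column.
    """
    if len(class_labels) != len(cross_result.individual_id):
        raise ValueError("one class label per individual required")
    classes = list(dict.fromkeys(class_labels))
    if len(classes) < 1:
        raise ValueError("no classes present")
    q1 = np.asarray(cross_result.q1)
    rows, samples = [], {}
    for cls in classes:
        vals = q1[np.array([c == cls for c in class_labels])]
        samples[cls] = vals
        rows.append(
            {
                "class": cls,
                "n": len(vals),
                "q_min": float(vals.min()),
                "q_max": float(vals.max()),
                "lo": float(np.quantile(vals, quantiles[0])),
                "hi": float(np.quantile(vals, quantiles[1])),
                "mean": float(vals.mean()),
                "wide_range_flag": len(vals) < min_class_n,
            }
        )
    import warnings

    for r in rows:
        if r["wide_range_flag"]:
            warnings.warn(
                f"class {r['class']!r}: only {r['n']} individuals; range unstable"
            )
    return ClassRangeTable(
        pd.DataFrame(rows).set_index("class"), quantiles, samples
    )


#: the printed verbal rule: elegans backcrosses >= 75%, the central
#: F1/first-backcross band 50-55%, graellsii backcrosses <= 25%
VERBAL_GROUPS = {
    "elegans_backcrosses": (0.75, 1.0),
    "F1_and_first_backcrosses": (0.50, 0.55),
    "graellsii_backcrosses": (0.0, 0.25),
}


def conservative_groups(
    ranges: ClassRangeTable | None = None, preset: str = "verbal"
) -> dict[str, tuple[float, float]]:
    """Assignment-group boundaries.

    ``verbal`` reproduces the printed rule (with unassigned gaps between
    groups); ``quantile`` keys three contiguous bands to the F1 class's
    empirical quantile range: below it graellsii-backcross-like, inside it
    F1-like, above it elegans-backcross-like.
    """
    if preset == "verbal":
        return dict(VERBAL_GROUPS)
    if preset == "quantile":
        if ranges is None or "F1" not in ranges.table.index:
            raise ValueError("quantile preset needs class ranges including F1")
        lo, hi = ranges.range_of("F1")
        return {
            "elegans_backcrosses": (hi, 1.0),
            "F1_and_first_backcrosses": (lo, hi),
            "graellsii_backcrosses": (0.0, lo),
        }
    raise ValueError(f"unknown preset {preset!r}")


def classify_by_class_ranges(
    result: AdmixtureResult,
    ranges: ClassRangeTable,
    groups: dict[str, tuple[float, float]] | None = None,
    resolve_ties: bool = True,
) -> pd.DataFrame:
    """Assign each individual to cross classes and conservative groups.

    An individual receives every class whose quantile range contains its
    Q1 (multi-label); with ``resolve_ties`` the single best class is the
    one whose simulated Q1 distribution has the highest kernel density at
    the individual's value.  A Q1 outside all class ranges yields the
    ``"unassigned"`` label.  Group bounds are inclusive; a value on the
    shared boundary of two contiguous groups goes to the upper band.
    """
    groups = groups or conservative_groups(ranges, preset="verbal")
    kdes = {}
    for cls, vals in ranges.samples.items():
        if len(vals) > 2 and np.std(vals) > 1e-9:
            kdes[cls] = gaussian_kde(vals)
    rows = []
    for ind, pop, q in zip(result.individual_id, result.population, result.q1):
        classes = [
            cls
            for cls in ranges.table.index
            if ranges.table.loc[cls, "lo"] <= q <= ranges.table.loc[cls, "hi"]
        ]
        if not classes:
            best = "unassigned"
        elif len(classes) == 1 or not resolve_ties:
            best = classes[0]
        else:
            best = max(
                classes,
                key=lambda c: float(kdes[c](q)[0]) if c in kdes else -np.inf,
            )
        in_groups = [g for g, (lo, hi) in groups.items() if lo <= q <= hi]
        # a value on a shared boundary of contiguous groups goes to the
        # upper band
        in_groups.sort(key=lambda g: groups[g][0], reverse=True)
        rows.append(
            {
                "individual": ind,
                "population": pop,
                "Q1": q,
                "classes": ";".join(classes) if classes else "unassigned",
                "best_class": best,
                "group": in_groups[0] if in_groups else "unassigned",
            }
        )
    return pd.DataFrame(rows)
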