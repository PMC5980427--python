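"""Diversity, differentiation, linkage-disequilibrium and isolation-by-
distance statistics for diploid multilocus panels.

Differentiation uses the Weir & Cockerham (1984) variance-components
estimator theta and Jost's D (with Nei-Chesser bias correction and
harmonic-mean sample sizes), both with percentile bootstrap confidence
intervals over loci.  Genotypic linkage disequilibrium is tested per locus
pair with a Markov chain over genotype-by-genotype contingency tables with
fixed margins (Diaconis-Sturmfels swap moves, G statistic), combined
across a region's populations by Fisher's method.  Isolation by distance
is a one-tailed Mantel permutation test on great-circle distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypePanel, PopulationMetadata

__all__ = [
    "LDChainParams",
    "PairwiseStatMatrix",
    "LDTestResult",
    "MantelResult",
    "diversity_summary",
    "pairwise_fst",
    "pairwise_dest",
    "wc_theta",
    "jost_d",
    "ld_pair_test",
    "region_ld_scan",
    "mantel_ibd",
    "great_circle_km",
]


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def diversity_summary(panel: GenotypePanel) -> pd.DataFrame:
    """Per-population N, total allele count, Ho, He and unbiased He.

    Ho is the fraction of heterozygous single-locus genotypes among fully
    typed ones, averaged over loci; He = 1 - sum(p^2) per locus, averaged;
    uHe applies the 2n/(2n-1) small-sample correction per locus before
    averaging.  Loci with no typed genotypes in a population are skipped
    with a warning.
    """
    rows = []
    for pop in panel.populations:
        sub = panel.select_populations([pop])
        g = sub.genotypes
        ho_l, he_l, uhe_l = [], [], []
        n_alleles = 0
        for l in range(sub.n_loci):
            gl = g[:, l, :]
            typed = (gl != MISSING).all(axis=1)
            if not typed.any():
                warnings.warn(
                    f"population {pop!r}: locus {sub.locus_names[l]!r} untyped, skipped"
                )
                continue
            gl = gl[typed]
            n = len(gl)
            ho_l.append(float((gl[:, 0] != gl[:, 1]).mean()))
            _, counts = np.unique(gl.ravel(), return_counts=True)
            n_alleles += len(counts)
            p = counts / counts.sum()
            he = 1.0 - float((p**2).sum())
            he_l.append(he)
            uhe_l.append(2 * n / (2 * n - 1) * he if n > 1 else he)
        rows.append(
            {
                "population": pop,
                "species": sub.species_label[0],
                "N": sub.n_individuals,
                "alleles": n_alleles,
                "Ho": float(np.mean(ho_l)),
                "He": float(np.mean(he_l)),
                "uHe": float(np.mean(uhe_l)),
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


def _locus_counts(panel: GenotypePanel, pops: list[str]):
    """Per locus: allele codes, per-pop sample sizes, allele freqs and
    heterozygote-carrier freqs.  Yields one record per usable locus."""
    subs = [panel.select_populations([p]) for p in pops]
    for l in range(panel.n_loci):
        data = []
        for sub in subs:
            gl = sub.genotypes[:, l, :]
            typed = (gl != MISSING).all(axis=1)
            data.append(gl[typed])
        ns = np.array([len(d) for d in data])
        if (ns < 2).any():
            yield None  # undersampled locus: contributes zeros
            continue
        alleles = np.unique(np.concatenate([d.ravel() for d in data]))
        if len(alleles) < 2:
            yield None  # monomorphic: contributes zeros
            continue
        p = np.zeros((len(data), len(alleles)))
        h = np.zeros((len(data), len(alleles)))
        for i, d in enumerate(data):
            for j, a in enumerate(alleles):
                p[i, j] = (d == a).mean()
                h[i, j] = ((d[:, 0] != d[:, 1]) & ((d == a).any(axis=1))).mean()
        yield ns, p, h


def _wc_components(ns: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham (1984) a, b, c summed over the alleles of one locus."""
    r = len(ns)
    nbar = ns.mean()
    nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
    pbar = (ns[:, None] * p).sum(axis=0) / ns.sum()
    s2 = (ns[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ns[:, None] * h).sum(axis=0) / ns.sum()
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_theta(panel: GenotypePanel, pops: list[str] | None = None):
    """Multilocus Weir-Cockerham theta over the given populations.

    Returns (theta, per-locus (a, a+b+c) arrays).  Negative estimates are
    reported as computed.
    """
    pops = pops or panel.populations
    num, den = [], []
    for rec in _locus_counts(panel, pops):
        if rec is None:
            num.append(0.0)
            den.append(0.0)
            continue
        a, b, c = _wc_components(*rec)
        num.append(a)
        den.append(a + b + c)
    num, den = np.array(num), np.array(den)
    if den.sum() == 0:
        return 0.0, (num, den)
    return float(num.sum() / den.sum()), (num, den)


def jost_d(panel: GenotypePanel, pops: list[str] | None = None):
    """Multilocus Jost's D (mean over loci) with Nei-Chesser correction.

    Per locus: Hs and Ht from per-population frequencies, Hs corrected by
    2n~/(2n~ - 1) with n~ the harmonic-mean sample size, Ht by adding
    Hs_est / (2 n~ r); D = (Ht_est - Hs_est) / (1 - Hs_est) * r / (r - 1).
    """
    pops = pops or panel.populations
    r = len(pops)
    d_loci = []
    for rec in _locus_counts(panel, pops):
        if rec is None:
            d_loci.append(0.0)
            continue
        ns, p, _ = rec
        nh = r / (1.0 / ns).sum()
        hs = float(np.mean(1.0 - (p**2).sum(axis=1)))
        pbar = p.mean(axis=0)
        ht = 1.0 - float((pbar**2).sum())
        hs_est = 2 * nh / (2 * nh - 1) * hs
        ht_est = ht + hs_est / (2 * nh * r)
        if hs_est >= 1.0:
            d_loci.append(0.0)
            continue
        d_loci.append((ht_est - hs_est) / (1 - hs_est) * r / (r - 1))
    return float(np.mean(d_loci)), np.array(d_loci)


@dataclass
class PairwiseStatMatrix:
    """Symmetric pairwise differentiation matrix with bootstrap CIs."""

    statistic: str  # FST_WC | Dest_Jost
    populations: list[str]
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.estimate, index=self.populations, columns=self.populations
        )

    def lower_triangle(self) -> np.ndarray:
        iu = np.tril_indices(len(self.populations), k=-1)
        return self.estimate[iu]


def _pairwise_matrix(
    panel: GenotypePanel, statistic: str, n_bootstrap: int, seed: int
) -> PairwiseStatMatrix:
    rng = np.random.default_rng(seed)
    pops = []
    for p in panel.populations:
        if panel.select_populations([p]).n_individuals < 2:
            warnings.warn(f"population {p!r} has < 2 individuals; excluded")
        else:
            pops.append(p)
    if len(pops) < 2:
        raise ValueError("need at least two populations of >= 2 individuals")
    k = len(pops)
    est = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        if statistic == "FST_WC":
            point, (num, den) = wc_theta(panel, [pops[i], pops[j]])

            def ratio(idx, num=num, den=den):
                d = den[idx].sum()
                return num[idx].sum() / d if d > 0 else 0.0

        else:
            point, d_loci = jost_d(panel, [pops[i], pops[j]])

            def ratio(idx, d_loci=d_loci):
                return float(d_loci[idx].mean())

        L = panel.n_loci
        boots = np.array(
            [ratio(rng.integers(0, L, size=L)) for _ in range(n_bootstrap)]
        )
        est[i, j] = est[j, i] = point
        lo[i, j] = lo[j, i] = float(np.percentile(boots, 2.5))
        hi[i, j] = hi[j, i] = float(np.percentile(boots, 97.5))
    return PairwiseStatMatrix(statistic, pops, est, lo, hi, n_bootstrap)


def pairwise_fst(
    panel: GenotypePanel, n_bootstrap: int = 1000, seed: int = 0
) -> PairwiseStatMatrix:
    """Pairwise Weir-Cockerham theta with 95% percentile bootstrap CIs
    (resampling loci)."""
    return _pairwise_matrix(panel, "FST_WC", n_bootstrap, seed)


def pairwise_dest(
    panel: GenotypePanel, n_bootstrap: int = 1000, seed: int = 0
) -> PairwiseStatMatrix:
    """Pairwise Jost's D with 95% percentile bootstrap CIs."""
    return _pairwise_matrix(panel, "Dest_Jost", n_bootstrap, seed)


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LDChainParams:
    """Markov chain settings for the genotypic LD exact test."""

    dememorization: int = 1000
    n_batches: int = 100
    iterations_per_batch: int = 1000


def _genotype_table(panel: GenotypePanel, la: int, lb: int, pop: str):
    sub = panel.select_populations([pop])
    ga = np.sort(sub.genotypes[:, la, :], axis=1)
    gb = np.sort(sub.genotypes[:, lb, :], axis=1)
    ok = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
    ga, gb = ga[ok], gb[ok]
    if len(ga) == 0:
        return None
    _, ia = np.unique(ga, axis=0, return_inverse=True)
    _, ib = np.unique(gb, axis=0, return_inverse=True)
    table = np.zeros((ia.max() + 1, ib.max() + 1), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    n_alleles_a = len(np.unique(ga))
    n_alleles_b = len(np.unique(gb))
    return table, n_alleles_a, n_alleles_b


def locus_pair_testable(panel: GenotypePanel, la: int, lb: int, pop: str) -> bool:
    """Both loci polymorphic in the population after missing-data removal."""
    rec = _genotype_table(panel, la, lb, pop)
    if rec is None:
        return False
    _, na, nb = rec
    return na >= 2 and nb >= 2


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G against row-column independence."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return float(2.0 * terms.sum())


def _xlogx_sum(table: np.ndarray) -> float:
    t = table[table > 0].astype(float)
    return float((t * np.log(t)).sum())


try:  # jitted swap chain; the pure-python fallback is ~100x slower
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _swap_chain(table, s_obs, demem, n_batches, iters, seed):  # pragma: no cover
    """Metropolis chain over fixed-margin tables; returns batch hit means.

    State weight is the hypergeometric 1 / prod(x_ij!); the statistic
    tracked is sum x log x, equivalent to G once margins are fixed.
    """
    np.random.seed(seed)
    r, c = table.shape
    x = table.copy()
    s = 0.0
    for i in range(r):
        for j in range(c):
            if x[i, j] > 0:
                s += x[i, j] * np.log(x[i, j])
    batch_means = np.zeros(n_batches)
    eps = 1e-9
    total = demem + n_batches * iters
    hits = 0
    count = 0
    for step in range(total):
        i1 = np.random.randint(r)
        i2 = np.random.randint(r - 1)
        if i2 >= i1:
            i2 += 1
        j1 = np.random.randint(c)
        j2 = np.random.randint(c - 1)
        if j2 >= j1:
            j2 += 1
        if np.random.randint(2) == 0:
            # x[i1,j1]+1, x[i1,j2]-1, x[i2,j1]-1, x[i2,j2]+1
            if x[i1, j2] > 0 and x[i2, j1] > 0:
                ratio = (x[i1, j2] * x[i2, j1]) / (
                    (x[i1, j1] + 1.0) * (x[i2, j2] + 1.0)
                )
                if np.random.random() < ratio:
                    for (a, b, d) in (
                        (i1, j1, 1),
                        (i1, j2, -1),
                        (i2, j1, -1),
                        (i2, j2, 1),
                    ):
                        if x[a, b] > 0:
                            s -= x[a, b] * np.log(x[a, b])
                        x[a, b] += d
                        if x[a, b] > 0:
                            s += x[a, b] * np.log(x[a, b])
        else:
            if x[i1, j1] > 0 and x[i2, j2] > 0:
                ratio = (x[i1, j1] * x[i2, j2]) / (
                    (x[i1, j2] + 1.0) * (x[i2, j1] + 1.0)
                )
                if np.random.random() < ratio:
                    for (a, b, d) in (
                        (i1, j1, -1),
                        (i1, j2, 1),
                        (i2, j1, 1),
                        (i2, j2, -1),
                    ):
                        if x[a, b] > 0:
                            s -= x[a, b] * np.log(x[a, b])
                        x[a, b] += d
                        if x[a, b] > 0:
                            s += x[a, b] * np.log(x[a, b])
        if step >= demem:
            k = step - demem
            if s >= s_obs - eps:
                hits += 1
            count += 1
            if count == iters:
                batch_means[k // iters] = hits / iters
                hits = 0
                count = 0
    return batch_means


@dataclass
class LDTestResult:
    """Genotypic LD test for one locus pair (per population or combined)."""

    locus_a: str
    locus_b: str
    population: str | None
    g: float
    p: float
    se: float
    chain: LDChainParams | None = None
    per_population: list["LDTestResult"] = field(default_factory=list)
    testable: bool = True


def ld_pair_test(
    panel: GenotypePanel,
    locus_a: str,
    locus_b: str,
    population: str,
    chain_params: LDChainParams | None = None,
    seed: int = 0,
) -> LDTestResult:
    """Markov-chain exact test of genotypic association for one locus pair
    within one population.

    p is the chain estimate of the probability of a table (margins fixed)
    with G at least as large as observed; the SE is the batch-mean standard
    error.
    """
    cp = chain_params or LDChainParams()
    la = panel.locus_names.index(locus_a)
    lb = panel.locus_names.index(locus_b)
    rec = _genotype_table(panel, la, lb, population)
    if rec is None:
        raise ValueError(f"no complete genotypes in {population!r}")
    table, na, nb = rec
    if na < 2 or nb < 2:
        return LDTestResult(locus_a, locus_b, population, 0.0, 1.0, 0.0, cp, testable=False)
    g_obs = g_statistic(table)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return LDTestResult(locus_a, locus_b, population, g_obs, 1.0, 0.0, cp)
    s_obs = _xlogx_sum(table)
    batches = _swap_chain(
        table.astype(np.int64),
        s_obs,
        cp.dememorization,
        cp.n_batches,
        cp.iterations_per_batch,
        int(seed) % (2**31 - 1),
    )
    p = float(batches.mean())
    se = float(batches.std(ddof=1) / math.sqrt(len(batches))) if len(batches) > 1 else 0.0
    return LDTestResult(locus_a, locus_b, population, g_obs, p, se, cp)


def region_ld_scan(
    panel: GenotypePanel,
    region_populations: list[str],
    chain_params: LDChainParams | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[LDTestResult], pd.DataFrame]:
    """Test every testable locus pair across a region's populations.

    A pair is testable when both loci are polymorphic in at least one
    population of the region.  Per-population p-values are combined with
    Fisher's method.  Returns the combined results and a summary frame
    with raw and Bonferroni significance counts.
    """
    cp = chain_params or LDChainParams()
    rng = np.random.default_rng(seed)
    results: list[LDTestResult] = []
    n_samples = cp.n_batches * cp.iterations_per_batch
    for la, lb in combinations(range(panel.n_loci), 2):
        name_a, name_b = panel.locus_names[la], panel.locus_names[lb]
        per_pop = []
        for pop in region_populations:
            if locus_pair_testable(panel, la, lb, pop):
                per_pop.append(
                    ld_pair_test(
                        panel, name_a, name_b, pop, cp, seed=int(rng.integers(2**31 - 1))
                    )
                )
        if not per_pop:
            continue
        ps = np.array([max(t.p, 1.0 / (n_samples + 1)) for t in per_pop])
        chi2 = float(-2.0 * np.log(ps).sum())
        p_comb = float(stats.chi2.sf(chi2, df=2 * len(ps)))
        results.append(
            LDTestResult(
                name_a,
                name_b,
                None,
                chi2,
                p_comb,
                0.0,
                cp,
                per_population=per_pop,
            )
        )
    n_pairs = len(results)
    n_sig = sum(1 for t in results if t.p < alpha)
    n_bonf = sum(1 for t in results if t.p < alpha / max(n_pairs, 1))
    summary = pd.DataFrame(
        [
            {
                "n_testable_pairs": n_pairs,
                "n_significant": n_sig,
                "n_significant_bonferroni": n_bonf,
                "alpha": alpha,
            }
        ]
    )
    return results, summary


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in kilometres."""
    r = 6371.0088
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(min(1.0, math.sqrt(a)))


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    populations: list[str]
    tail: str = "one_sided_greater"


def mantel_ibd(
    stat_matrix: PairwiseStatMatrix,
    metadata: list[PopulationMetadata],
    n_permutations: int = 9999,
    seed: int = 0,
    drop: list[str] | None = None,
) -> MantelResult:
    """One-tailed (greater) Mantel test of differentiation against
    great-circle distance, permuting population labels.

    ``drop`` removes populations before testing (outlier re-analysis).
    """
    drop = set(drop or [])
    meta = {m.population: m for m in metadata}
    pops = [p for p in stat_matrix.populations if p not in drop]
    missing = [p for p in pops if p not in meta]
    if missing:
        raise ValueError(f"no coordinates for populations {missing}")
    if len(pops) < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    idx = [stat_matrix.populations.index(p) for p in pops]
    s = stat_matrix.estimate[np.ix_(idx, idx)]
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mi, mj = meta[pops[i]], meta[pops[j]]
            d[i, j] = d[j, i] = great_circle_km(
                mi.latitude, mi.longitude, mj.latitude, mj.longitude
            )
    iu = np.tril_indices(k, k=-1)
    r_obs = float(np.corrcoef(d[iu], s[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        sp = s[np.ix_(perm, perm)]
        if np.corrcoef(d[iu], sp[iu])[0, 1] >= r_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return MantelResult(r_obs, float(p), n_permutations, pops)
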