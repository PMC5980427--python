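"""Maximum-entropy niche models, overlap statistics, and the niche
identity and background similarity randomization tests.

The model is a desk-scale maxent: features are the standardized linear and
quadratic terms of each environmental variable, the raw distribution over
background cells is ``q(x) proportional to exp(lambda . f(x))``, and the
weights minimize the L1-penalized negative mean presence log-likelihood (a
convex problem solved with L-BFGS-B on a positive/negative weight split).
Overlap between two models uses Schoener's D and the modified Hellinger I
on raw surfaces renormalized over a common cell set.

The identity test pools and repartitions two occurrence sets; the
background similarity test compares the observed cross-group overlap with
overlaps against models fit on random draws from the other group's
background region (two-tailed: low tail = divergence, high tail =
conservatism).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import EnvStack, OccurrenceSet

__all__ = [
    "NicheModelConfig",
    "NicheModel",
    "OverlapResult",
    "sample_background_points",
    "prune_correlated_variables",
    "fit_maxent_lite",
    "auc_presence_background",
    "select_model_grid",
    "overlap_stats",
    "suitability_surface",
    "identity_test",
    "background_similarity_test",
]


@dataclass
class NicheModelConfig:
    """Settings for one maxent-lite fit."""

    features: str = "linear+quadratic"  # or "linear"
    beta: float = 1.0
    tau: float = 0.5  # logistic-output prevalence
    n_background: int = 10000
    tolerance: float = 1e-5
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.features not in ("linear", "linear+quadratic"):
            raise ValueError("features must be linear|linear+quadratic")


@dataclass
class NicheModel:
    """A fitted maxent-lite model."""

    config: NicheModelConfig
    variable_names: list[str]
    feature_names: list[str]
    weights: np.ndarray
    feature_mean: np.ndarray  # background standardization
    feature_sd: np.ndarray
    background_cells: np.ndarray  # (m, 2) row/col
    q_background: np.ndarray  # raw distribution over background cells
    entropy: float
    train_auc: float
    n_presence: int
    converged: bool = True

    def _features(self, stack: EnvStack, cells: np.ndarray) -> np.ndarray:
        raw = np.column_stack(
            [stack.variables[v][cells[:, 0], cells[:, 1]] for v in self.variable_names]
        )
        z = (raw - self.feature_mean[: raw.shape[1]]) / self.feature_sd[: raw.shape[1]]
        if self.config.features == "linear+quadratic":
            nv = raw.shape[1]
            zq = (raw - self.feature_mean[:nv]) ** 2
            zq = (zq - self.feature_mean[nv:]) / self.feature_sd[nv:]
            z = np.column_stack([z, zq])
        return z

    def raw_scores(self, stack: EnvStack, cells: np.ndarray) -> np.ndarray:
        """Unnormalized log-suitability lambda . f at the given cells."""
        return self._features(stack, cells) @ self.weights

    def raw_surface(self, stack: EnvStack, cells: np.ndarray) -> np.ndarray:
        """Raw distribution over an arbitrary cell set (normalized on it)."""
        s = self.raw_scores(stack, cells)
        w = np.exp(s - s.max())
        return w / w.sum()

    def logistic_surface(self, stack: EnvStack, cells: np.ndarray) -> np.ndarray:
        """Prevalence-tuned logistic output in [0, 1]."""
        s = self.raw_scores(stack, cells)
        # q relative to the training background normalizer
        sb = self.raw_scores(stack, self.background_cells)
        logz = np.log(np.exp(sb - sb.max()).sum()) + sb.max()
        q = np.exp(s - logz)
        tau = self.config.tau
        eh_q = np.exp(self.entropy) * q
        return tau * eh_q / (1.0 - tau + tau * eh_q)


def sample_background_points(
    stack: EnvStack, n: int = 10000, seed: int = 0, with_replacement: bool | None = None
) -> np.ndarray:
    """Uniform background sample over non-nodata cells; (n, 2) row/col.

    Without replacement when the landscape has at least ``n`` data cells;
    smaller landscapes fall back to using every cell unless replacement is
    requested explicitly.
    """
    cells = stack.valid_cells()
    if len(cells) == 0:
        raise ValueError("landscape has no data cells")
    rng = np.random.default_rng(seed)
    if len(cells) <= n:
        if with_replacement:
            return cells[rng.integers(0, len(cells), size=n)]
        return cells
    pick = rng.choice(len(cells), size=n, replace=False)
    return cells[pick]


def prune_correlated_variables(
    stack: EnvStack, points: np.ndarray, threshold: float = 0.7
) -> list[str]:
    """Greedy elimination of variables with |Pearson r| above threshold.

    While any pair exceeds the threshold at the sampled cells, the member
    of the worst pair with the larger mean absolute correlation to all
    remaining variables is dropped; ties break alphabetically (the later
    name goes).
    """
    names = list(stack.variables)
    if len(names) < 2:
        return names
    data = {n: stack.variables[n][points[:, 0], points[:, 1]] for n in names}
    keep = sorted(names)
    while len(keep) > 1:
        mat = np.corrcoef(np.array([data[n] for n in keep]))
        np.fill_diagonal(mat, 0.0)
        amax = np.abs(mat)
        i, j = np.unravel_index(np.argmax(amax), amax.shape)
        if amax[i, j] <= threshold:
            break
        mean_abs = amax.mean(axis=0)
        if mean_abs[i] > mean_abs[j]:
            drop = keep[i]
        elif mean_abs[j] > mean_abs[i]:
            drop = keep[j]
        else:
            drop = max(keep[i], keep[j])
        keep.remove(drop)
    return [n for n in names if n in keep]


def fit_maxent_lite(
    stack: EnvStack,
    occurrences: OccurrenceSet,
    config: NicheModelConfig | None = None,
    background: np.ndarray | None = None,
) -> NicheModel:
    """Fit the L1-penalized maximum-entropy model.

    Presences are deduplicated per cell before fitting.  The per-feature
    penalty scale is the presence standard deviation of the standardized
    feature divided by the square root of the presence count, so the
    penalty vanishes as evidence accumulates.
    """
    cfg = config or NicheModelConfig()
    cells_p = occurrences.cells(stack)
    quadratic = cfg.features == "linear+quadratic"
    nv = len(stack.variables)
    n_feat = 2 * nv if quadratic else nv
    if len(cells_p) < max(10, n_feat + 1):
        raise ValueError(
            f"{len(cells_p)} presence cells after deduplication; "
            f"need at least {max(10, n_feat + 1)}"
        )
    if background is None:
        background = sample_background_points(stack, cfg.n_background, cfg.seed)

    names = list(stack.variables)
    raw_b = stack.features_at(background)
    raw_p = stack.features_at(cells_p)
    mean_lin = raw_b.mean(axis=0)
    sd_lin = np.where(raw_b.std(axis=0) > 0, raw_b.std(axis=0), 1.0)
    if quadratic:
        sq_b = (raw_b - mean_lin) ** 2
        mean_q = sq_b.mean(axis=0)
        sd_q = np.where(sq_b.std(axis=0) > 0, sq_b.std(axis=0), 1.0)
        fmean = np.concatenate([mean_lin, mean_q])
        fsd = np.concatenate([sd_lin, sd_q])
        fb = np.column_stack([(raw_b - mean_lin) / sd_lin, (sq_b - mean_q) / sd_q])
        sq_p = (raw_p - mean_lin) ** 2
        fp = np.column_stack([(raw_p - mean_lin) / sd_lin, (sq_p - mean_q) / sd_q])
        feat_names = [f"{n}" for n in names] + [f"{n}^2" for n in names]
    else:
        fmean, fsd = mean_lin, sd_lin
        fb = (raw_b - mean_lin) / sd_lin
        fp = (raw_p - mean_lin) / sd_lin
        feat_names = list(names)

    # zero-variance presence features carry no signal: drop from the fit
    pres_sd = fp.std(axis=0)
    active = pres_sd > 1e-12
    m = len(fp)
    scale = np.where(active, pres_sd, 1.0) / np.sqrt(m)
    penalty = cfg.beta * scale

    fbar = fp.mean(axis=0)
    n_iter = [0]

    def objective(w):
        lam = w[:n_feat] - w[n_feat:]
        s = fb @ lam
        smax = s.max()
        logz = smax + np.log(np.exp(s - smax).sum())
        nll = -(fbar @ lam) + logz
        grad_lam = -fbar + (np.exp(s - logz) @ fb)
        g = np.concatenate([grad_lam + penalty, -grad_lam + penalty])
        return nll + penalty @ (w[:n_feat] + w[n_feat:]), g

    w0 = np.zeros(2 * n_feat)
    bounds = [(0.0, None if a else 0.0) for a in active] * 2
    res = optimize.minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=lambda xk: n_iter.__setitem__(0, n_iter[0] + 1),
        options={"maxiter": cfg.max_iterations, "ftol": cfg.tolerance * 1e-3,
                 "gtol": cfg.tolerance},
    )
    converged = bool(res.success) or res.status == 0
    if not converged and "ITERATIONS" in str(res.message).upper():
        warnings.warn("maxent-lite did not converge within max_iterations")
    lam = res.x[:n_feat] - res.x[n_feat:]

    s = fb @ lam
    w = np.exp(s - s.max())
    q = w / w.sum()
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())

    model = NicheModel(
        config=cfg,
        variable_names=names,
        feature_names=feat_names,
        weights=lam,
        feature_mean=fmean,
        feature_sd=fsd,
        background_cells=background,
        q_background=q,
        entropy=entropy,
        train_auc=0.0,
        n_presence=len(cells_p),
        converged=converged,
    )
    model.train_auc = auc_presence_background(model, stack, cells_p, background)
    return model


def auc_presence_background(
    model: NicheModel, stack: EnvStack, presence_cells: np.ndarray, background: np.ndarray
) -> float:
    """Rank-based (Mann-Whitney) AUC of presence vs background scores;
    ties count one half."""
    sp = model.raw_scores(stack, presence_cells)
    sb = model.raw_scores(stack, background)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("need at least one presence and one background point")
    allv = np.concatenate([sp, sb])
    if np.ptp(allv) == 0:
        return 0.5
    from scipy.stats import rankdata

    ranks = rankdata(allv)
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2
    return float(u / (len(sp) * len(sb)))


def select_model_grid(
    stack: EnvStack,
    occurrences: OccurrenceSet,
    tau_grid=(0.5, 0.6, 0.7),
    beta_grid=(1.0, 2.0, 3.0),
    seed: int = 0,
    base_config: NicheModelConfig | None = None,
) -> tuple[NicheModel, pd.DataFrame]:
    """Fit every (tau, beta) combination and keep the highest training AUC.

    Rank AUC is invariant to the monotone logistic rescale, so tau cannot
    change AUC; ties resolve to the smaller beta then the smaller tau
    (fewest effective parameters).  The grid report lists every fit.
    """
    if not tau_grid or not beta_grid:
        raise ValueError("grids must be non-empty")
    base = base_config or NicheModelConfig(seed=seed)
    background = sample_background_points(stack, base.n_background, seed)
    rows, fits = [], {}
    for beta in beta_grid:
        for tau in tau_grid:
            cfg = replace(base, beta=float(beta), tau=float(tau), seed=seed)
            model = fit_maxent_lite(stack, occurrences, cfg, background=background)
            fits[(beta, tau)] = model
            rows.append(
                {
                    "beta": beta,
                    "tau": tau,
                    "auc": model.train_auc,
                    "n_nonzero_weights": int((np.abs(model.weights) > 1e-8).sum()),
                    "converged": model.converged,
                }
            )
    report = pd.DataFrame(rows)
    best_key = max(
        fits, key=lambda k: (round(fits[k].train_auc, 12), -k[0], -k[1])
    )
    return fits[best_key], report


# ---------------------------------------------------------------------------
# overlap and randomization tests
# ---------------------------------------------------------------------------


def suitability_surface(model: NicheModel, stack: EnvStack, cells: np.ndarray):
    return model.raw_surface(stack, cells)


def overlap_stats(p_x: np.ndarray, p_y: np.ndarray) -> tuple[float, float]:
    """Schoener's D and modified Hellinger I between two probability
    surfaces on a common cell set.

    D = 1 - 0.5 sum |px - py|; I = 1 - 0.5 sum (sqrt(px) - sqrt(py))^2.
    Both are 1 for identical surfaces and 0 for disjoint supports.
    """
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    if p_x.shape != p_y.shape:
        raise ValueError("surfaces must share a cell set")
    sx, sy = p_x.sum(), p_y.sum()
    if sx <= 0 or sy <= 0:
        return 0.0, 0.0
    p_x, p_y = p_x / sx, p_y / sy
    d = 1.0 - 0.5 * float(np.abs(p_x - p_y).sum())
    i = 1.0 - 0.5 * float(((np.sqrt(p_x) - np.sqrt(p_y)) ** 2).sum())
    return d, i


def model_overlap(
    model_x: NicheModel, model_y: NicheModel, stack: EnvStack, cells: np.ndarray
) -> tuple[float, float]:
    return overlap_stats(
        model_x.raw_surface(stack, cells), model_y.raw_surface(stack, cells)
    )


@dataclass
class OverlapResult:
    """Observed D/I with a permutation or randomization null."""

    test: str  # identity | background_similarity
    group_x: str
    group_y: str
    d_observed: float
    i_observed: float
    null_d: np.ndarray
    null_i: np.ndarray
    p_d: float
    p_i: float
    verdict_d: str
    verdict_i: str
    alpha: float
    direction: str | None = None  # for background test: which group's region

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "a": self.group_x,
            "b": self.group_y,
            "D": self.d_observed,
            "I": self.i_observed,
            "p_D": self.p_d,
            "p_I": self.p_i,
            "verdict_D": self.verdict_d,
            "verdict_I": self.verdict_i,
        }


def _refit(stack, points, group, config, background):
    occ = OccurrenceSet(group=group, points=points)
    return fit_maxent_lite(stack, occ, config, background=background)


def identity_test(
    stack: EnvStack,
    occ_x: OccurrenceSet,
    occ_y: OccurrenceSet,
    config: NicheModelConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
) -> OverlapResult:
    """Niche identity (equivalency) test.

    The null pools both occurrence sets and randomly repartitions the
    points into the original sizes, refitting both models each time.  The
    one-tailed p is ``(1 + #{null <= observed}) / (n_reps + 1)``; a low
    observed overlap rejects identity.
    """
    if occ_x.n_points == 0 or occ_y.n_points == 0:
        raise ValueError("both occurrence sets must be non-empty")
    if n_reps < 30:
        warnings.warn("fewer than 30 pseudoreplicates: coarse p resolution")
    cfg = config or NicheModelConfig()
    rng = np.random.default_rng(seed)
    background = sample_background_points(stack, cfg.n_background, seed)
    cells = stack.valid_cells()

    mx = _refit(stack, occ_x.points, occ_x.group, cfg, background)
    my = _refit(stack, occ_y.points, occ_y.group, cfg, background)
    d_obs, i_obs = model_overlap(mx, my, stack, cells)

    pooled = np.vstack([occ_x.points, occ_y.points])
    nx = occ_x.n_points
    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(pooled))
        ma = _refit(stack, pooled[perm[:nx]], "null_a", cfg, background)
        mb = _refit(stack, pooled[perm[nx:]], "null_b", cfg, background)
        null_d[r], null_i[r] = model_overlap(ma, mb, stack, cells)
    p_d = (1 + int((null_d <= d_obs).sum())) / (n_reps + 1)
    p_i = (1 + int((null_i <= i_obs).sum())) / (n_reps + 1)
    verdict = lambda p: "not_identical" if p < alpha else "not_significant"
    return OverlapResult(
        "identity",
        occ_x.group,
        occ_y.group,
        d_obs,
        i_obs,
        null_d,
        null_i,
        float(p_d),
        float(p_i),
        verdict(p_d),
        verdict(p_i),
        alpha,
    )


def background_similarity_test(
    stack: EnvStack,
    occ_x: OccurrenceSet,
    occ_y: OccurrenceSet,
    region_y: tuple[float, float, float, float] | None = None,
    config: NicheModelConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> OverlapResult:
    """Background similarity test of x's niche against y's background.

    The null refits y's model on |occ_y| cells drawn uniformly from y's
    background region (default: the bounding box of y's occurrences
    expanded by 10% per side) and recomputes the overlap with x's model.
    Two-tailed verdicts: observed below the alpha/2 null quantile means
    divergence, above 1 - alpha/2 conservatism, otherwise not significant.
    """
    cfg = config or NicheModelConfig()
    rng = np.random.default_rng(seed)
    background = sample_background_points(stack, cfg.n_background, seed)
    cells = stack.valid_cells()

    if region_y is None:
        x0, y0 = occ_y.points.min(axis=0)
        x1, y1 = occ_y.points.max(axis=0)
        pad_x, pad_y = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
        region_y = (x0 - pad_x, x1 + pad_x, y0 - pad_y, y1 + pad_y)
    rx0, rx1, ry0, ry1 = region_y
    centers = np.array([stack.cell_center(r, c) for r, c in cells])
    in_region = (
        (centers[:, 0] >= rx0)
        & (centers[:, 0] <= rx1)
        & (centers[:, 1] >= ry0)
        & (centers[:, 1] <= ry1)
    )
    region_cells = cells[in_region]
    region_centers = centers[in_region]
    if len(region_cells) < occ_y.n_points:
        raise ValueError(
            f"background region holds {len(region_cells)} cells for "
            f"{occ_y.n_points} points"
        )

    mx = _refit(stack, occ_x.points, occ_x.group, cfg, background)
    my = _refit(stack, occ_y.points, occ_y.group, cfg, background)
    d_obs, i_obs = model_overlap(mx, my, stack, cells)

    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.integers(0, len(region_cells), size=occ_y.n_points)
        mb = _refit(stack, region_centers[pick], "null_bg", cfg, background)
        null_d[r], null_i[r] = model_overlap(mx, mb, stack, cells)

    def verdict(obs, null):
        lo = np.quantile(null, alpha / 2)
        hi = np.quantile(null, 1 - alpha / 2)
        if obs < lo:
            return "divergence"
        if obs > hi:
            return "conservatism"
        return "not_significant"

    rank_low_d = (1 + int((null_d <= d_obs).sum())) / (n_reps + 1)
    rank_low_i = (1 + int((null_i <= i_obs).sum())) / (n_reps + 1)
    p_d = float(min(1.0, 2 * min(rank_low_d, 1 - rank_low_d + 1 / (n_reps + 1))))
    p_i = float(min(1.0, 2 * min(rank_low_i, 1 - rank_low_i + 1 / (n_reps + 1))))
    return OverlapResult(
        "background_similarity",
        occ_x.group,
        occ_y.group,
        d_obs,
        i_obs,
        null_d,
        null_i,
        p_d,
        p_i,
        verdict(d_obs, null_d),
        verdict(i_obs, null_i),
        alpha,
        direction=f"{occ_x.group} vs background of {occ_y.group}",
    )
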