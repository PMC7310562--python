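"""Expression heterochrony: time-shift estimation between species.

For each gene the workflow is
(1) screen for an age effect with polynomial regression on log2 age
    (degree 1-3 chosen by adjusted r-squared, F-test against the
    intercept-only model);
(2) screen for species divergence with an ANCOVA-style partial F-test
    (species main effect + species x age-polynomial interaction);
(3) for genes passing both screens, fit per-species polynomial trajectories,
    evaluate them on a common grid over the overlapping log2-age range,
    z-score the two curves and align them with dynamic time warping
    (symmetric steps, both endpoints pinned); the time shift is the mean
    signed displacement along the warping path, in log2-age units —
    positive means the human trajectory is delayed (neoteny), negative
    means it is accelerated;
(4) assess shift significance with a parametric bootstrap under the null of
    a shared trajectory (pooled polynomial fit plus per-species residual
    resampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DataError, ExpressionDataset

ALPHA = 0.05  # screening and heterochrony significance threshold


@dataclass
class GeneScreenResult:
    gene: str
    age_pvalue: float
    best_degree: int
    adj_r2: float
    species_pvalue: float

    @property
    def passes(self) -> bool:
        return self.age_pvalue < ALPHA and self.species_pvalue < ALPHA


@dataclass
class HeterochronyCall:
    gene: str
    shift_log2age: float  # positive = human trajectory delayed
    shift_pvalue: float
    klass: str  # "acceleration" | "neoteny" | "none"


def log2_age(ages_pcd: np.ndarray) -> np.ndarray:
    """log2 of age in postconception days (the developmental clock used
    throughout the heterochrony analysis)."""
    ages_pcd = np.asarray(ages_pcd, dtype=float)
    if np.any(ages_pcd <= 0):
        raise DataError("ages must be positive to take log2")
    return np.log2(ages_pcd)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def age_related_test(
    expr: np.ndarray, log2ages: np.ndarray, max_degree: int = 3
) -> tuple[float, int, float]:
    """Polynomial-regression age screen.

    Fits degrees 1..3 (capped so that the design stays overdetermined on
    the distinct ages available), picks the degree maximizing adjusted
    r-squared, and returns the F-test p-value of that model against the
    intercept-only model, the chosen degree, and its adjusted r-squared.
    """
    expr = np.asarray(expr, dtype=float)
    u = np.asarray(log2ages, dtype=float)
    n = expr.size
    n_distinct = np.unique(u).size
    usable = min(max_degree, n_distinct - 2)
    if usable < 1:
        raise DataError("need at least 3 distinct ages for the age screen")
    if usable < max_degree:
        import warnings

        warnings.warn(
            f"only {n_distinct} distinct ages; capping polynomial degree at {usable}",
            stacklevel=2,
        )
    tss = float(np.sum((expr - expr.mean()) ** 2))
    best = None  # (adj_r2, degree, rss)
    for deg in range(1, usable + 1):
        coefs = np.polyfit(u, expr, deg)
        rss = float(np.sum((expr - np.polyval(coefs, u)) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        dof = n - deg - 1
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else -np.inf
        if best is None or adj > best[0]:
            best = (adj, deg, rss)
    adj_r2, degree, rss = best
    dof = n - degree - 1
    if tss <= 0:
        return 1.0, degree, 0.0
    if rss <= 1e-300 * tss:
        return 0.0, degree, adj_r2
    f = ((tss - rss) / degree) / (rss / dof)
    p = float(stats.f.sf(f, degree, dof))
    return p, degree, adj_r2


def species_divergence_test(
    expr_h: np.ndarray,
    log2ages_h: np.ndarray,
    expr_m: np.ndarray,
    log2ages_m: np.ndarray,
    degree: int,
) -> float:
    """ANCOVA species screen: partial F-test of all species terms.

    Full model: age polynomial plus a species main effect and species x
    polynomial interactions.  Reduced model: the shared age polynomial.
    """
    expr_h = np.asarray(expr_h, dtype=float)
    expr_m = np.asarray(expr_m, dtype=float)
    if expr_h.size < degree + 2 or expr_m.size < degree + 2:
        raise DataError("each species needs at least degree+2 samples")
    u = np.concatenate([log2ages_h, log2ages_m])
    u = u - u.mean()  # center for conditioning
    y = np.concatenate([expr_h, expr_m])
    species = np.concatenate([np.zeros(expr_h.size), np.ones(expr_m.size)])

    poly = np.column_stack([u**d for d in range(1, degree + 1)])
    x_reduced = np.column_stack([np.ones_like(u), poly])
    x_full = np.column_stack([x_reduced, species, poly * species[:, None]])

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    rss_r, rss_f = rss(x_reduced), rss(x_full)
    q = degree + 1  # species terms added
    df2 = y.size - x_full.shape[1]
    if df2 <= 0:
        raise DataError("rank-deficient design: too few samples for the ANCOVA")
    if rss_f <= 0:
        return 0.0 if rss_r > rss_f else 1.0
    f = ((rss_r - rss_f) / q) / (rss_f / df2)
    return float(stats.f.sf(max(f, 0.0), q, df2))


def screen_genes(
    ds_h: ExpressionDataset, ds_m: ExpressionDataset
) -> list[GeneScreenResult]:
    """Run both screens for every shared gene."""
    shared = [g for g in ds_h.gene_ids if g in set(ds_m.gene_ids)]
    hidx = {g: i for i, g in enumerate(ds_h.gene_ids)}
    midx = {g: i for i, g in enumerate(ds_m.gene_ids)}
    u_h, u_m = log2_age(ds_h.ages), log2_age(ds_m.ages)
    u_all = np.concatenate([u_h, u_m])
    results = []
    for g in shared:
        eh, em = ds_h.values[hidx[g]], ds_m.values[midx[g]]
        p_age, degree, adj = age_related_test(np.concatenate([eh, em]), u_all)
        p_sp = species_divergence_test(eh, u_h, em, u_m, degree)
        results.append(GeneScreenResult(g, p_age, degree, adj, p_sp))
    return results


# ---------------------------------------------------------------------------
# DTW shift
# ---------------------------------------------------------------------------


def _dtw_mean_displacement(
    human_curves: np.ndarray, macaque_curves: np.ndarray, trim: float = 0.1
) -> np.ndarray:
    """Batched DTW: mean signed path displacement (index units) per curve pair.

    ``human_curves`` and ``macaque_curves`` have shape (K, G).  Symmetric
    step pattern (diagonal, up, left), both endpoints pinned.  For every
    cell the DP tracks, along the optimal path, the running sum of
    (human index - macaque index) and the path length, so no backtracking
    is needed.  Ties prefer the diagonal step.

    The displacement is averaged over the interior of the warping path
    (cells whose indices both lie at least ``trim`` of the grid away from
    the ends): the pinned endpoints force the displacement to zero at the
    corners, which would otherwise bias the statistic toward zero.  The
    full-path average is the fallback when a degenerate path avoids the
    interior band.
    """
    h = np.asarray(human_curves, dtype=float)
    m = np.asarray(macaque_curves, dtype=float)
    if h.ndim == 1:
        h, m = h[None, :], m[None, :]
    k, g = h.shape
    cost = np.abs(h[:, :, None] - m[:, None, :])  # (K, G, G)
    margin = int(trim * g)
    if 2 * margin >= g:
        margin = 0

    def inside(i: int, j: int) -> bool:
        return margin <= i <= g - 1 - margin and margin <= j <= g - 1 - margin

    d = np.full((k, g, g), np.inf)
    s = np.zeros((k, g, g))  # sum of (i - j) along full path
    ln = np.zeros((k, g, g))  # full path length
    si = np.zeros((k, g, g))  # sum of (i - j) over interior cells
    li = np.zeros((k, g, g))  # interior path length
    d[:, 0, 0] = cost[:, 0, 0]
    ln[:, 0, 0] = 1.0
    for j in range(1, g):
        d[:, 0, j] = d[:, 0, j - 1] + cost[:, 0, j]
        s[:, 0, j] = s[:, 0, j - 1] - j
        ln[:, 0, j] = ln[:, 0, j - 1] + 1.0
        if inside(0, j):
            si[:, 0, j] = si[:, 0, j - 1] - j
            li[:, 0, j] = li[:, 0, j - 1] + 1.0
        else:
            si[:, 0, j] = si[:, 0, j - 1]
            li[:, 0, j] = li[:, 0, j - 1]
    rng_k = np.arange(k)
    for i in range(1, g):
        d[:, i, 0] = d[:, i - 1, 0] + cost[:, i, 0]
        s[:, i, 0] = s[:, i - 1, 0] + i
        ln[:, i, 0] = ln[:, i - 1, 0] + 1.0
        if inside(i, 0):
            si[:, i, 0] = si[:, i - 1, 0] + i
            li[:, i, 0] = li[:, i - 1, 0] + 1.0
        else:
            si[:, i, 0] = si[:, i - 1, 0]
            li[:, i, 0] = li[:, i - 1, 0]
        for j in range(1, g):
            cand = np.stack([d[:, i - 1, j - 1], d[:, i - 1, j], d[:, i, j - 1]])
            choice = np.argmin(cand, axis=0)  # ties -> diagonal
            d[:, i, j] = cand[choice, rng_k] + cost[:, i, j]
            s[:, i, j] = (
                np.stack([s[:, i - 1, j - 1], s[:, i - 1, j], s[:, i, j - 1]])[choice, rng_k]
                + (i - j)
            )
            ln[:, i, j] = (
                np.stack([ln[:, i - 1, j - 1], ln[:, i - 1, j], ln[:, i, j - 1]])[choice, rng_k]
                + 1.0
            )
            add = 1.0 if inside(i, j) else 0.0
            si[:, i, j] = (
                np.stack([si[:, i - 1, j - 1], si[:, i - 1, j], si[:, i, j - 1]])[choice, rng_k]
                + add * (i - j)
            )
            li[:, i, j] = (
                np.stack([li[:, i - 1, j - 1], li[:, i - 1, j], li[:, i, j - 1]])[choice, rng_k]
                + add
            )
    interior_len = li[:, -1, -1]
    full = s[:, -1, -1] / ln[:, -1, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        trimmed = si[:, -1, -1] / interior_len
    return np.where(interior_len > 0, trimmed, full)


def _fitted_curves(
    expr: np.ndarray, log2ages: np.ndarray, degree: int, grid: np.ndarray
) -> np.ndarray:
    coefs = np.polyfit(log2ages, expr, degree)
    return np.polyval(coefs, grid)


def _zscore_curve(curve: np.ndarray) -> np.ndarray | None:
    sd = curve.std()
    if sd < 1e-10:
        return None
    return (curve - curve.mean()) / sd


def dtw_shift(
    expr_h: np.ndarray,
    ages_h: np.ndarray,
    expr_m: np.ndarray,
    ages_m: np.ndarray,
    degree: int,
    n_grid: int = 50,
) -> float | None:
    """Estimate the heterochronic time shift of one gene, in log2-age units.

    Per-species polynomial fits are evaluated on a common ``n_grid``-point
    grid over the overlapping log2-age range, z-scored, and aligned by DTW;
    the shift is the mean signed displacement along the warping path mapped
    back to log2-age units.  Returns ``None`` if either fitted curve is
    flat (shift undefined) and raises on non-overlapping age ranges.
    """
    u_h, u_m = log2_age(ages_h), log2_age(ages_m)
    lo, hi = max(u_h.min(), u_m.min()), min(u_h.max(), u_m.max())
    if hi <= lo:
        raise DataError("species age ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)
    curve_h = _zscore_curve(_fitted_curves(expr_h, u_h, degree, grid))
    curve_m = _zscore_curve(_fitted_curves(expr_m, u_m, degree, grid))
    if curve_h is None or curve_m is None:
        return None
    disp = _dtw_mean_displacement(curve_h, curve_m)[0]
    return float(disp / (n_grid - 1) * (hi - lo))


def shift_significance(
    expr_h: np.ndarray,
    ages_h: np.ndarray,
    expr_m: np.ndarray,
    ages_m: np.ndarray,
    degree: int,
    observed_shift: float,
    n_sims: int = 1000,
    seed: int = 0,
    n_grid: int = 50,
) -> float:
    """Parametric-bootstrap p-value for an estimated shift.

    The null is a shared trajectory: a pooled polynomial fit over both
    species, with per-species residuals resampled with replacement.  The
    shift statistic is recomputed for each simulated dataset and the
    p-value is the add-one-corrected fraction of |null shifts| >= |observed|.
    """
    if n_sims < 100:
        raise DataError("n_sims must be at least 100 for a usable p-value")
    rng = np.random.default_rng(seed)
    u_h, u_m = log2_age(ages_h), log2_age(ages_m)
    lo, hi = max(u_h.min(), u_m.min()), min(u_h.max(), u_m.max())
    if hi <= lo:
        raise DataError("species age ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)

    pooled_u = np.concatenate([u_h, u_m])
    pooled_y = np.concatenate([expr_h, expr_m])
    coefs = np.polyfit(pooled_u, pooled_y, degree)
    fit_h, fit_m = np.polyval(coefs, u_h), np.polyval(coefs, u_m)
    res_h, res_m = expr_h - fit_h, expr_m - fit_m
    # dof-corrected residual scaling: fitted residuals have deflated
    # variance, which would make the bootstrap anti-conservative
    p = degree + 1
    if res_h.size > p:
        res_h = res_h * np.sqrt(res_h.size / (res_h.size - p))
    if res_m.size > p:
        res_m = res_m * np.sqrt(res_m.size / (res_m.size - p))

    sim_h = fit_h[None, :] + rng.choice(res_h, size=(n_sims, res_h.size), replace=True)
    sim_m = fit_m[None, :] + rng.choice(res_m, size=(n_sims, res_m.size), replace=True)

    # batched per-species polynomial fits (np.polyfit accepts 2-D y)
    ch = np.polyfit(u_h, sim_h.T, degree)  # (degree+1, n_sims)
    cm = np.polyfit(u_m, sim_m.T, degree)
    vand = np.vander(grid, degree + 1)
    curves_h = (vand @ ch).T  # (n_sims, n_grid)
    curves_m = (vand @ cm).T

    def _z(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = rows.std(axis=1, keepdims=True)
        flat = sd[:, 0] < 1e-10
        z = (rows - rows.mean(axis=1, keepdims=True)) / np.where(sd < 1e-10, 1.0, sd)
        return z, flat

    zh, flat_h = _z(curves_h)
    zm, flat_m = _z(curves_m)
    disp = _dtw_mean_displacement(zh, zm)
    null_shifts = disp / (n_grid - 1) * (hi - lo)
    null_shifts[flat_h | flat_m] = 0.0
    exceed = int(np.sum(np.abs(null_shifts) >= abs(observed_shift)))
    return (1 + exceed) / (n_sims + 1)


def classify(shift: float | None, pvalue: float, alpha: float = ALPHA) -> str:
    """Neoteny iff shift > 0 and p < alpha; acceleration iff shift < 0 and
    p < alpha; otherwise none (including undefined shifts)."""
    if shift is None or not pvalue < alpha:
        return "none"
    if shift > 0:
        return "neoteny"
    if shift < 0:
        return "acceleration"
    return "none"


def call_heterochrony(
    ds_h: ExpressionDataset,
    ds_m: ExpressionDataset,
    n_sims: int = 1000,
    seed: int = 0,
    genes: list[str] | None = None,
    screen: bool = True,
    n_grid: int = 50,
) -> tuple[list[GeneScreenResult], list[HeterochronyCall]]:
    """Screen genes and produce shift calls for those passing both screens.

    ``genes`` restricts the analysis; ``screen=False`` bypasses the screens
    (shifts and p-values are then computed for every requested gene, which
    is what calibration studies need).
    """
    screens = screen_genes(
        ds_h if genes is None else ds_h.subset_genes(genes),
        ds_m if genes is None else ds_m.subset_genes(genes),
    )
    hidx = {g: i for i, g in enumerate(ds_h.gene_ids)}
    midx = {g: i for i, g in enumerate(ds_m.gene_ids)}
    calls = []
    for i, sc in enumerate(screens):
        if screen and not sc.passes:
            continue
        eh, em = ds_h.values[hidx[sc.gene]], ds_m.values[midx[sc.gene]]
        shift = dtw_shift(eh, ds_h.ages, em, ds_m.ages, sc.best_degree, n_grid)
        if shift is None:
            calls.append(HeterochronyCall(sc.gene, float("nan"), 1.0, "none"))
            continue
        p = shift_significance(
            eh, ds_h.ages, em, ds_m.ages, sc.best_degree, shift,
            n_sims=n_sims, seed=seed + i, n_grid=n_grid,
        )
        calls.append(HeterochronyCall(sc.gene, shift, p, classify(shift, p)))
    return screens, calls
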