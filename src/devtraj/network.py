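"""Co-expression modules, modular differential connectivity, and
mutual-information key-driver analysis.

Module detection follows the weighted co-expression recipe: soft-threshold
the |correlation| matrix to approximate scale-free topology, convert to the
topological overlap matrix (TOM), cluster genes on 1 - TOM and cut the
tree at a fixed height with a minimum module size.

Modular differential connectivity (MDC) compares a module's mean pairwise
connectivity (|corr|^power) between the early and late stage on a log2
scale, so MDC > 0 is a gain of early co-regulation and MDC < 0 a loss.

Within a module, an unweighted interaction network is built from pairwise
mutual information (rank-based Gaussian-copula estimator), thresholded by
a permutation null, and pruned with the data processing inequality (the
weakest edge of each triangle is removed when clearly dominated).  Key
drivers are genes whose N-hop neighborhood is unusually large.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import DataError, ExpressionDataset


@dataclass
class ModuleSet:
    """Gene -> module assignment (0 = unassigned) plus per-module MDC."""

    assignment: dict[str, int]
    soft_power: int
    module_mdc: dict[int, tuple[float, str]] = field(default_factory=dict)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.assignment.items():
            if m > 0:
                out.setdefault(m, []).append(g)
        return out


@dataclass
class MINetwork:
    """Unweighted (post-DPI) mutual-information network over module genes."""

    graph: nx.Graph
    nodes: list[str]
    hubs: list[str] = field(default_factory=list)
    early_specific_hubs: list[str] = field(default_factory=list)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


# ---------------------------------------------------------------------------
# covariates & adjacency
# ---------------------------------------------------------------------------


def regress_out_covariates(ds: ExpressionDataset, covariates: np.ndarray) -> ExpressionDataset:
    """Per-gene linear residualization on the given covariate columns
    (samples x covariates); the gene mean is retained."""
    import dataclasses as _dc

    cov = np.asarray(covariates, dtype=float)
    if cov.shape[0] != ds.n_samples:
        raise DataError("covariate rows must match sample count")
    x = np.column_stack([np.ones(ds.n_samples), cov])
    beta, *_ = np.linalg.lstsq(x, ds.values.T, rcond=None)
    resid = ds.values - (x[:, 1:] @ beta[1:, :]).T
    return _dc.replace(ds, values=resid)


def _abs_corr_genes(expr: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr)
    return np.abs(np.nan_to_num(corr, nan=0.0))


def pick_soft_power(
    expr: np.ndarray,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest soft-threshold power whose connectivity distribution fits
    scale-free topology with model r^2 >= ``target_r2``.

    The fit regresses log10 frequency on log10 mean connectivity over
    equal-width connectivity bins and requires a negative slope.  Falls
    back to the max-r^2 power with a warning when no power reaches the
    target.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 20:
        raise DataError("need at least 20 genes to assess scale-free fit")
    acorr = _abs_corr_genes(expr)
    best_power, best_r2 = powers[0], -np.inf
    for p in powers:
        adj = acorr**p
        k = adj.sum(axis=1) - 1.0
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= target_r2:
            return p
        if r2 > best_r2:
            best_power, best_r2 = p, r2
    warnings.warn(
        f"no power reached scale-free r2 {target_r2}; using power {best_power} "
        f"(r2={best_r2:.3f})",
        stacklevel=2,
    )
    return best_power


def _scale_free_r2(connectivity: np.ndarray, n_bins: int) -> float:
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return -np.inf
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(math.log10(members.mean()))
        ys.append(math.log10(members.size / k.size))
    if len(xs) < 3:
        return -np.inf
    slope, _, r, *_ = stats.linregress(xs, ys)
    if slope >= 0:
        return 0.0
    return float(r**2)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with unit diagonal.  The input must be square, symmetric, in
    [0, 1], with zero diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DataError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise DataError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise DataError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.95,
    soft_power: int = 6,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters surviving the ``min_module_size`` filter are numbered 1..K by
    decreasing size; everything else is module 0.
    """
    tom = np.asarray(tom, dtype=float)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(np.maximum(dist, 0.0), checks=False), method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    sizes = [
        (int((flat == lab).sum()), int(lab))
        for lab in np.unique(flat)
        if (flat == lab).sum() >= min_module_size
    ]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    relabel = {lab: i + 1 for i, (_, lab) in enumerate(sizes)}
    assignment = {
        g: relabel.get(int(lab), 0) for g, lab in zip(gene_ids, flat)
    }
    return ModuleSet(assignment=assignment, soft_power=soft_power)


def build_modules(
    early: ExpressionDataset,
    min_module_size: int = 30,
    cut_height: float = 0.95,
    target_r2: float = 0.8,
) -> ModuleSet:
    """Convenience: pick the soft power on early-stage data, form the TOM,
    and detect modules."""
    power = pick_soft_power(early.values, target_r2=target_r2)
    adj = _abs_corr_genes(early.values) ** power
    np.fill_diagonal(adj, 0.0)
    tom = topological_overlap(adj)
    return detect_modules(tom, early.gene_ids, min_module_size, cut_height, power)


# ---------------------------------------------------------------------------
# modular differential connectivity
# ---------------------------------------------------------------------------


def mdc(
    module_genes: list[str],
    early: ExpressionDataset,
    late: ExpressionDataset,
    soft_power: int = 6,
    tau: float = 0.1,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, str]:
    """Modular differential connectivity of one module.

    Connectivity of a gene pair is the soft adjacency |corr|^power computed
    within each stage; MDC = log2(mean early connectivity / mean late
    connectivity).  Class: gain when the whole (1 - ``alpha``) stage-wise
    bootstrap confidence interval of the log ratio lies above ``tau``, loss
    when it lies below ``-tau``, none otherwise.

    The interval gate matters because a factor-driven module's pairwise
    correlations all reflect one latent sample path, so the connectivity
    ratio has substantial sampling noise that a fixed threshold alone
    cannot separate from a genuine connectivity change.  Zero late
    connectivity yields +inf (flagged as gain).
    """
    if len(module_genes) < 3:
        raise DataError("module needs at least 3 genes for MDC")
    if early.n_samples < 4 or late.n_samples < 4:
        raise DataError("each stage needs at least 4 samples for MDC")

    expr_e = early.subset_genes(module_genes).values
    expr_l = late.subset_genes(module_genes).values

    def mean_connectivity(expr: np.ndarray) -> float:
        adj = _abs_corr_genes(expr) ** soft_power
        iu = np.triu_indices(adj.shape[0], k=1)
        return float(adj[iu].mean())

    def log_ratio(expr_a: np.ndarray, expr_b: np.ndarray) -> float:
        ca, cb = mean_connectivity(expr_a), mean_connectivity(expr_b)
        if cb <= 0:
            return math.inf
        # difference of logs (not log of ratio) so antisymmetry is exact
        return math.log2(ca) - math.log2(cb)

    value = log_ratio(expr_e, expr_l)
    if math.isinf(value):
        return value, "gain"

    rng = np.random.default_rng(seed)
    ne, nl = expr_e.shape[1], expr_l.shape[1]
    boot = np.empty(n_perm)
    for b in range(n_perm):
        boot[b] = log_ratio(
            expr_e[:, rng.integers(0, ne, ne)], expr_l[:, rng.integers(0, nl, nl)]
        )
    boot = boot[np.isfinite(boot)]
    if boot.size < n_perm // 2:
        return value, "none"
    lo, hi = np.quantile(boot, [alpha / 2, 1.0 - alpha / 2])
    if lo > tau and value > tau:
        return value, "gain"
    if hi < -tau and value < -tau:
        return value, "loss"
    return value, "none"


def score_modules(
    modules: ModuleSet,
    early: ExpressionDataset,
    late: ExpressionDataset,
    tau: float = 0.1,
) -> ModuleSet:
    """Fill ``module_mdc`` for every detected module."""
    for mid, genes in sorted(modules.modules().items()):
        modules.module_mdc[mid] = mdc(genes, early, late, modules.soft_power, tau)
    return modules


# ---------------------------------------------------------------------------
# mutual-information network & key drivers
# ---------------------------------------------------------------------------


def _copula_mi_matrix(expr: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian-copula MI: -0.5 log(1 - rho*^2), with rho* the
    Pearson-equivalent of the Spearman correlation (2 sin(pi rho_s / 6))."""
    ranks = np.apply_along_axis(stats.rankdata, 1, expr)
    with np.errstate(invalid="ignore"):
        rho_s = np.corrcoef(ranks)
    rho_s = np.nan_to_num(rho_s, nan=0.0)
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
    rho = np.clip(rho, -0.999999, 0.999999)
    mi = -0.5 * np.log(1.0 - rho**2)
    np.fill_diagonal(mi, 0.0)
    return mi


def _null_mi_threshold(
    n_samples: int, n_pairs: int, alpha: float, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation null for the copula MI with Bonferroni-style quantile.

    Null MIs come from correlating independently permuted rank vectors;
    the threshold is the (1 - alpha / n_pairs) quantile of the null.
    """
    base = np.arange(1, n_samples + 1, dtype=float)
    r1 = np.stack([rng.permutation(base) for _ in range(n_perm)])
    r2 = np.stack([rng.permutation(base) for _ in range(n_perm)])
    z1 = (r1 - r1.mean(axis=1, keepdims=True)) / r1.std(axis=1, keepdims=True)
    z2 = (r2 - r2.mean(axis=1, keepdims=True)) / r2.std(axis=1, keepdims=True)
    rho_s = (z1 * z2).mean(axis=1)
    rho = np.clip(2.0 * np.sin(np.pi * rho_s / 6.0), -0.999999, 0.999999)
    null_mi = -0.5 * np.log(1.0 - rho**2)
    q = min(1.0 - alpha / max(n_pairs, 1), 1.0 - 1.0 / n_perm)
    return float(np.quantile(null_mi, q))


def mi_network(
    expr: np.ndarray,
    gene_ids: list[str],
    dpi_tolerance: float = 0.15,
    alpha: float = 0.05,
    n_perm: int = 20000,
    seed: int = 0,
) -> MINetwork:
    """Significant-MI network with data-processing-inequality pruning.

    Edges are kept when their MI exceeds a permutation-derived threshold;
    then, in every triangle, the weakest edge is deleted if it is weaker
    than both other edges by the factor (1 - ``dpi_tolerance``), the usual
    indirect-interaction rule.
    """
    expr = np.asarray(expr, dtype=float)
    n_genes, n_samples = expr.shape
    if n_genes < 3:
        raise DataError("need at least 3 genes for a network")
    if n_samples < 8:
        raise DataError("need at least 8 samples to estimate MI")
    rng = np.random.default_rng(seed)
    mi = _copula_mi_matrix(expr)
    n_pairs = n_genes * (n_genes - 1) // 2
    thr = _null_mi_threshold(n_samples, n_pairs, alpha, n_perm, rng)

    weights = np.where(mi > thr, mi, 0.0)
    np.fill_diagonal(weights, 0.0)

    # DPI: scan triangles on the thresholded graph, mark dominated edges.
    present = weights > 0
    to_remove: set[tuple[int, int]] = set()
    idx = np.arange(n_genes)
    for i in idx:
        js = idx[(idx > i) & present[i]]
        for j in js:
            ks = idx[(idx > j) & present[i] & present[j]]
            for k in ks:
                wij, wik, wjk = weights[i, j], weights[i, k], weights[j, k]
                trio = [(wij, (i, j)), (wik, (i, k)), (wjk, (j, k))]
                trio.sort(key=lambda t: t[0])
                wmin, emin = trio[0]
                if wmin < (1.0 - dpi_tolerance) * trio[1][0] and wmin < (
                    1.0 - dpi_tolerance
                ) * trio[2][0]:
                    to_remove.add(emin)

    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if present[i, j] and (i, j) not in to_remove:
                graph.add_edge(gene_ids[i], gene_ids[j], weight=float(weights[i, j]))
    return MINetwork(graph=graph, nodes=list(gene_ids))


def key_drivers(net: MINetwork, hops: int = 2, sd_mult: float = 1.0) -> list[str]:
    """Genes with an unusually large <=``hops``-hop neighborhood.

    A gene is a hub when its neighborhood size exceeds the mean plus
    ``sd_mult`` standard deviations over all genes.  The hub list is also
    stored on the network.
    """
    if not net.nodes:
        raise DataError("empty network")
    sizes = {}
    for g in net.nodes:
        if g in net.graph:
            reach = nx.single_source_shortest_path_length(net.graph, g, cutoff=hops)
            sizes[g] = len(reach) - 1  # exclude self
        else:
            sizes[g] = 0
    vals = np.array([sizes[g] for g in net.nodes], dtype=float)
    cut = vals.mean() + sd_mult * vals.std()
    hubs = [g for g in net.nodes if sizes[g] > cut]
    net.hubs = hubs
    return hubs


def neighborhood_sizes(net: MINetwork, hops: int = 2) -> dict[str, int]:
    """<=hops-hop neighborhood size (self excluded) for every gene."""
    out = {}
    for g in net.nodes:
        if g in net.graph:
            out[g] = len(nx.single_source_shortest_path_length(net.graph, g, cutoff=hops)) - 1
        else:
            out[g] = 0
    return out


def early_specific_hubs(
    early_net: MINetwork, late_net: MINetwork, hops: int = 2, sd_mult: float = 1.0
) -> list[str]:
    """Hubs of the early-stage network that are not hubs of the late-stage one."""
    eh = set(early_net.hubs or key_drivers(early_net, hops, sd_mult))
    lh = set(late_net.hubs or key_drivers(late_net, hops, sd_mult))
    result = [g for g in early_net.nodes if g in eh and g not in lh]
    early_net.early_specific_hubs = result
    return result
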