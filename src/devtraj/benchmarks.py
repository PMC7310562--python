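"""Reproducibility benchmarks: planted-truth recovery and exact oracles.

Every function here regenerates its inputs from the synthetic-data module
(or constructs the small exact cases directly), runs the corresponding
analysis stage, and measures recovery of the planted truth or agreement
with an independent oracle implementation.  The oracles (naive double-loop
composite index, exact combinatorial hypergeometric tail, brute-force
topological overlap, breadth-first neighborhood counting) are deliberately
separate code paths from the implementations they check.

These are the quantities reported by ``scripts/acceptance.py`` and
asserted by the acceptance test suite.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from fractions import Fraction

import numpy as np

from . import core, demarcation, dnb, enrichment, heterochrony, network, pipeline, simulate

# Study problem sizes (number of seeded replicate datasets per study).  The
# defaults match the package's documented evaluation protocol; smaller
# values are used by the quick unit checks.
N_SEEDS_DEMARCATION = 100
N_SEEDS_DNB_PEAK = 100
N_SEEDS_DNB_JACCARD = 50
N_SEEDS_DE = 50
N_SEEDS_MDC = 50
N_SEEDS_KEYDRIVER = 50
N_GENES_SHIFT = 200
N_GENES_NULL_SHIFT = 500


def _seed_stream(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds below 2**31, derived from one seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# 1. demarcation recovery
# ---------------------------------------------------------------------------


def demarcation_recovery(n_seeds: int = N_SEEDS_DEMARCATION, seed: int = 0) -> dict:
    """Fraction of seeded datasets (stage offset / noise = 2) whose recovered
    demarcation interval brackets the planted transition age."""
    hits = 0
    for s in _seed_stream(seed, n_seeds):
        cfg = dataclasses.replace(simulate.SimConfig(seed=s), switch_delta=0.6)
        ds_h, _, truth, _ = simulate.generate(cfg)
        z = core.log2_z_transform(core.filter_expressed(ds_h))
        result = demarcation.demarcate(z)[0]
        lo, hi = result.demarcation_interval
        hits += lo <= truth.transition_age["human"] <= hi
    return {"rate": hits / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# 2. DNB transition recovery
# ---------------------------------------------------------------------------


def _dnb_window_bounds(cfg: simulate.SimConfig) -> tuple[float, float]:
    grid = np.sort(np.unique(cfg.ages_human))
    i = int(np.argmin(np.abs(grid - cfg.transition_age_human)))
    return float(grid[max(i - 1, 0)]), float(grid[min(i + 1, grid.size - 1)])


def dnb_recovery(
    n_seeds_peak: int = N_SEEDS_DNB_PEAK,
    n_seeds_jaccard: int = N_SEEDS_DNB_JACCARD,
    seed: int = 0,
) -> dict:
    """CI-peak location and DNB-membership recovery at 20 replicates/age.

    The peak counts as recovered when its window center age falls inside
    the planted fluctuation region (one age-grid step either side of the
    transition age).  Membership recovery is the fraction of datasets with
    Jaccard(detected, planted) >= 0.6.
    """
    peak_hits = 0
    jaccard_hits = 0
    seeds = _seed_stream(seed, n_seeds_peak)
    for i, s in enumerate(seeds):
        cfg = dataclasses.replace(simulate.SimConfig(seed=s), replicates_per_age=20)
        ds_h, _, truth, _ = simulate.generate(cfg)
        z = core.log2_z_transform(ds_h)
        result = dnb.detect_transition(z)
        lo, hi = _dnb_window_bounds(cfg)
        peak_hits += lo <= result.transition_age_pcd <= hi
        if i < n_seeds_jaccard:
            got, planted = set(result.dnb_genes), set(truth.dnb_genes)
            union = got | planted
            jac = len(got & planted) / len(union) if union else 0.0
            jaccard_hits += jac >= 0.6
    return {
        "peak_rate": peak_hits / n_seeds_peak,
        "n_peak": n_seeds_peak,
        "jaccard_rate": jaccard_hits / n_seeds_jaccard,
        "n_jaccard": n_seeds_jaccard,
    }


# ---------------------------------------------------------------------------
# 3. composite-index oracle
# ---------------------------------------------------------------------------


def naive_composite_index(window_expr: np.ndarray, group: np.ndarray) -> tuple[float, float, float, float]:
    """Double-loop reference implementation of the composite index."""
    window_expr = np.asarray(window_expr, dtype=float)
    group = sorted(int(i) for i in group)
    out = [i for i in range(window_expr.shape[0]) if i not in set(group)]

    def pearson(x, y):
        xm, ym = x - x.mean(), y - y.mean()
        denom = math.sqrt(float(xm @ xm)) * math.sqrt(float(ym @ ym))
        return float(xm @ ym) / denom if denom > 0 else 0.0

    sds = []
    for i in group:
        x = window_expr[i]
        m = x.mean()
        sds.append(math.sqrt(float(((x - m) ** 2).sum()) / (x.size - 1)))
    sd_d = sum(sds) / len(sds)
    pairs = [
        abs(pearson(window_expr[i], window_expr[j]))
        for a, i in enumerate(group)
        for j in group[a + 1 :]
    ]
    pcc_d = sum(pairs) / len(pairs)
    cross = [abs(pearson(window_expr[i], window_expr[j])) for i in group for j in out]
    pcc_o = sum(cross) / len(cross)
    ci = math.inf if pcc_o == 0 else sd_d * pcc_d / pcc_o
    return sd_d, pcc_d, pcc_o, ci


def ci_oracle_equivalence(n_matrices: int = 100, seed: int = 0) -> dict:
    """Max abs difference between composite_index and the naive oracle on
    random 10x8 matrices with random groups."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        expr = rng.normal(size=(10, 8))
        size = int(rng.integers(2, 8))
        group = rng.choice(10, size=size, replace=False)
        score = dnb.composite_index(expr, group)
        ref = naive_composite_index(expr, group)
        worst = max(
            worst,
            abs(score.SD_d - ref[0]),
            abs(score.PCC_d - ref[1]),
            abs(score.PCC_o - ref[2]),
            abs(score.CI - ref[3]),
        )
    return {"max_abs_diff": worst, "n": n_matrices}


# ---------------------------------------------------------------------------
# 4. heterochrony
# ---------------------------------------------------------------------------


def shift_recovery(n_genes: int = N_GENES_SHIFT, seed: int = 0) -> dict:
    """Sign recovery and median |error| of the DTW shift on planted
    heterochronic genes (shift 1.0 log2-age, noise 0.3)."""
    errors: list[float] = []
    signs = 0
    seeds = iter(_seed_stream(seed, 1000))
    while len(errors) < n_genes:
        cfg = simulate.SimConfig(seed=next(seeds))
        ds_h, ds_m, truth, _ = simulate.generate(cfg)
        h, m = core.log2_transform(ds_h), core.log2_transform(ds_m)
        hidx = {g: i for i, g in enumerate(h.gene_ids)}
        u = np.concatenate([heterochrony.log2_age(h.ages), heterochrony.log2_age(m.ages)])
        for gene, true_shift in truth.shifts.items():
            if len(errors) >= n_genes:
                break
            eh, em = h.values[hidx[gene]], m.values[hidx[gene]]
            _, degree, _ = heterochrony.age_related_test(np.concatenate([eh, em]), u)
            est = heterochrony.dtw_shift(eh, h.ages, em, m.ages, degree)
            if est is None:
                est = 0.0
            errors.append(abs(est - true_shift))
            signs += np.sign(est) == np.sign(true_shift)
    return {
        "sign_rate": signs / n_genes,
        "median_abs_error": float(np.median(errors)),
        "n": n_genes,
    }


def shift_null_fpr(n_genes: int = N_GENES_NULL_SHIFT, n_sims: int = 1000, seed: int = 0) -> dict:
    """Fraction of null genes (shared trajectory) whose bootstrap shift
    p-value falls below 0.05."""
    fp = 0
    tested = 0
    seeds = iter(_seed_stream(seed, 1000))
    while tested < n_genes:
        s = next(seeds)
        cfg = simulate.SimConfig(seed=s)
        ds_h, ds_m, _, _ = simulate.null_dataset(cfg)
        h, m = core.log2_transform(ds_h), core.log2_transform(ds_m)
        u = np.concatenate([heterochrony.log2_age(h.ages), heterochrony.log2_age(m.ages)])
        for gi in range(0, min(100, h.n_genes)):
            if tested >= n_genes:
                break
            eh, em = h.values[gi], m.values[gi]
            _, degree, _ = heterochrony.age_related_test(np.concatenate([eh, em]), u)
            est = heterochrony.dtw_shift(eh, h.ages, em, m.ages, degree)
            if est is None:
                continue
            p = heterochrony.shift_significance(
                eh, h.ages, em, m.ages, degree, est, n_sims=n_sims, seed=s + gi
            )
            tested += 1
            fp += p < 0.05
    return {"fpr": fp / tested, "n": tested}


# ---------------------------------------------------------------------------
# 5. differential expression calibration & power
# ---------------------------------------------------------------------------


def de_calibration(n_seeds: int = N_SEEDS_DE, seed: int = 0) -> dict:
    """Null false-positive fraction at FDR 0.05 and planted switch-gene
    recall (log2 offset 1.0)."""
    fp_fracs = []
    recalls = []
    for s in _seed_stream(seed, n_seeds):
        cfg = simulate.SimConfig(seed=s)
        null_h, *_ = simulate.null_dataset(cfg)
        early, late = core.split_by_age(
            core.log2_transform(null_h), cfg.transition_age_human
        )
        null_de = enrichment.differential_expression(early, late)
        fp_fracs.append(float((null_de.table["fdr"] < 0.05).mean()))

        ds_h, _, truth, _ = simulate.generate(cfg)
        early, late = core.split_by_age(
            core.log2_transform(ds_h), cfg.transition_age_human
        )
        degs = enrichment.differential_expression(early, late)
        called = set(degs.significant().index)
        recalls.append(len(called & set(truth.switch_genes)) / len(truth.switch_genes))
    return {
        "null_fp_fraction": float(np.mean(fp_fracs)),
        "switch_recall": float(np.mean(recalls)),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# 6. Fisher / hypergeometric oracle
# ---------------------------------------------------------------------------


def exact_tail_pvalue(k: int, n_query: int, n_set: int, n_universe: int) -> float:
    """P(X >= k) by exact rational arithmetic over binomial coefficients."""
    total = Fraction(0)
    denom = math.comb(n_universe, n_query)
    for i in range(k, min(n_query, n_set) + 1):
        if n_query - i > n_universe - n_set:
            continue
        total += Fraction(
            math.comb(n_set, i) * math.comb(n_universe - n_set, n_query - i), denom
        )
    return float(min(total, Fraction(1)))


def fisher_oracle_equivalence(
    exhaustive_max_universe: int = 30,
    n_random: int = 2000,
    max_universe: int = 200,
    seed: int = 0,
) -> dict:
    """Max abs difference between the over-representation p-value and the
    exact combinatorial tail sum: every table with a small universe, plus a
    large random sample of tables with universe up to ``max_universe``."""
    worst = 0.0
    n_checked = 0
    for n_uni in range(2, exhaustive_max_universe + 1):
        for n_set in range(1, n_uni + 1):
            for n_query in range(1, n_uni + 1):
                for k in range(max(0, n_query + n_set - n_uni), min(n_query, n_set) + 1):
                    p = enrichment.overrep_pvalue(k, n_query, n_set, n_uni)
                    worst = max(worst, abs(p - exact_tail_pvalue(k, n_query, n_set, n_uni)))
                    n_checked += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n_uni = int(rng.integers(exhaustive_max_universe + 1, max_universe + 1))
        n_set = int(rng.integers(1, n_uni + 1))
        n_query = int(rng.integers(1, n_uni + 1))
        k_lo = max(0, n_query + n_set - n_uni)
        k_hi = min(n_query, n_set)
        k = int(rng.integers(k_lo, k_hi + 1))
        p = enrichment.overrep_pvalue(k, n_query, n_set, n_uni)
        worst = max(worst, abs(p - exact_tail_pvalue(k, n_query, n_set, n_uni)))
        n_checked += 1
    return {"max_abs_diff": worst, "n": n_checked}


# ---------------------------------------------------------------------------
# 7. TOM oracle, module recovery, MDC
# ---------------------------------------------------------------------------


def naive_tom(adjacency: np.ndarray) -> np.ndarray:
    """Brute-force double-loop topological overlap."""
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = [float(a[i].sum()) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def tom_oracle_equivalence(n_matrices: int = 50, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(4, 12))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        worst = max(
            worst, float(np.max(np.abs(network.topological_overlap(a) - naive_tom(a))))
        )
    return {"max_abs_diff": worst, "n": n_matrices}


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index from the contingency table."""
    from collections import Counter

    pairs = Counter(zip(labels_a, labels_b))
    ca, cb = Counter(labels_a), Counter(labels_b)
    n = len(labels_a)
    sum_comb = sum(math.comb(v, 2) for v in pairs.values())
    sum_a = sum(math.comb(v, 2) for v in ca.values())
    sum_b = sum(math.comb(v, 2) for v in cb.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


def _planted_block_data(
    rng: np.random.Generator,
    sizes: list[int],
    corr: float,
    n_noise: int,
    n_samples: int,
) -> tuple[np.ndarray, list[int]]:
    rows, labels = [], []
    for bi, size in enumerate(sizes):
        factor = rng.normal(size=n_samples)
        rows.append(
            np.sqrt(corr) * factor + np.sqrt(1 - corr) * rng.normal(size=(size, n_samples))
        )
        labels += [bi + 1] * size
    if n_noise:
        rows.append(rng.normal(size=(n_noise, n_samples)))
        labels += [0] * n_noise
    return np.vstack(rows), labels


def module_recovery_ari(n_repeats: int = 10, seed: int = 0) -> dict:
    """Mean assignment ARI of detect_modules on planted two-block data
    (50 + 50 genes at within-block correlation 0.7, 100 noise genes)."""
    aris = []
    for s in _seed_stream(seed, n_repeats):
        rng = np.random.default_rng(s)
        expr, labels = _planted_block_data(rng, [50, 50], 0.7, 100, 40)
        genes = [f"g{i}" for i in range(expr.shape[0])]
        adj = np.abs(np.corrcoef(expr)) ** 6
        np.fill_diagonal(adj, 0.0)
        modules = network.detect_modules(network.topological_overlap(adj), genes)
        pred = [modules.assignment[g] for g in genes]
        aris.append(adjusted_rand_index(labels, pred))
    return {"mean_ari": float(np.mean(aris)), "min_ari": float(np.min(aris)), "n": n_repeats}


def mdc_recovery(n_seeds: int = N_SEEDS_MDC, seed: int = 0) -> dict:
    """Planted gain/loss/none class recovery and exact MDC antisymmetry.

    Run at 3 replicates/age so each stage has >= 20 samples, the sample
    density at which the module-block structure is specified to be
    measurable.
    """
    ok = 0
    total = 0
    worst_antisym = 0.0
    for s in _seed_stream(seed, n_seeds):
        cfg = dataclasses.replace(simulate.SimConfig(seed=s), replicates_per_age=3)
        ds_h, _, truth, _ = simulate.generate(cfg)
        z = core.log2_z_transform(ds_h)
        early, late = core.split_by_age(z, cfg.transition_age_human)
        for name, (genes, klass) in truth.module_blocks.items():
            value, got = network.mdc(genes, early, late, soft_power=6, seed=s)
            total += 1
            ok += got == klass
            back, _ = network.mdc(genes, late, early, soft_power=6, seed=s)
            worst_antisym = max(worst_antisym, abs(value + back))
    return {
        "class_recovery": ok / total,
        "antisymmetry_max_abs": worst_antisym,
        "n": total,
    }


# ---------------------------------------------------------------------------
# 8. key drivers
# ---------------------------------------------------------------------------


def naive_neighborhood_sizes(edges: list[tuple[str, str]], nodes: list[str], hops: int) -> dict[str, int]:
    """Breadth-first search neighborhood counting, independent of networkx."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    sizes = {}
    for start in nodes:
        seen = {start}
        frontier = {start}
        for _ in range(hops):
            frontier = {w for v in frontier for w in adj[v]} - seen
            seen |= frontier
        sizes[start] = len(seen) - 1
    return sizes


def keydriver_recovery(n_seeds: int = N_SEEDS_KEYDRIVER, seed: int = 0) -> dict:
    """Star-graph exactness plus planted-regulator recovery.

    The planted regulator (the observed module factor) should rank in the
    top 5% of 2-hop neighborhood sizes in the early-stage MI network of
    the gain module; it should also be called an early-stage-specific hub.
    """
    import networkx as nx

    star = nx.star_graph(10)
    mapping = {i: f"n{i}" for i in star.nodes}
    net = network.MINetwork(
        graph=nx.relabel_nodes(star, mapping), nodes=list(mapping.values())
    )
    hubs = network.key_drivers(net, hops=1)
    star_exact = hubs == ["n0"]

    top5 = 0
    early_specific = 0
    for s in _seed_stream(seed, n_seeds):
        cfg = simulate.SimConfig(seed=s)
        ds_h, _, truth, _ = simulate.generate(cfg)
        z = core.log2_z_transform(ds_h)
        early, late = core.split_by_age(z, cfg.transition_age_human)
        gain = [m for m, (_, c) in truth.module_blocks.items() if c == "gain"][0]
        genes = truth.module_blocks[gain][0]
        regulator = truth.module_regulators[gain]
        e_net = network.mi_network(early.subset_genes(genes).values, genes, seed=s)
        l_net = network.mi_network(late.subset_genes(genes).values, genes, seed=s + 1)
        sizes = network.neighborhood_sizes(e_net, hops=2)
        cutoff_rank = max(1, int(np.ceil(0.05 * len(genes))))
        threshold = sorted(sizes.values(), reverse=True)[cutoff_rank - 1]
        top5 += sizes[regulator] >= threshold
        early_specific += regulator in network.early_specific_hubs(e_net, l_net)
    return {
        "star_exact": float(star_exact),
        "regulator_top5_rate": top5 / n_seeds,
        "early_specific_rate": early_specific / n_seeds,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# 9. end-to-end determinism
# ---------------------------------------------------------------------------


def e2e_determinism(seed: int = 0, work_dir: str = "scratch/e2e") -> dict:
    """Run the full pipeline twice with one seed; 1.0 when every stage
    output is byte-identical."""
    import hashlib
    from pathlib import Path

    work = Path(work_dir)
    paths = pipeline.make_demo(seed, work / "demo")
    outputs = [
        "demarcation.json",
        "dnb.json",
        "degs.tsv",
        "enrichment.tsv",
        "heterochrony.tsv",
        "modules.json",
        "key_drivers.json",
        "summary.json",
        "manifest.json",
    ]
    digests = []
    for run in ("run_a", "run_b"):
        cfg = pipeline.PipelineConfig(
            matrix=paths["human_matrix"],
            meta=paths["human_meta"],
            macaque_matrix=paths["macaque_matrix"],
            macaque_meta=paths["macaque_meta"],
            cell_means=paths["cell_means"],
            out_dir=str(work / run),
            seed=seed,
            hetero_sims=200,
        )
        pipeline.run_all(cfg)
        digests.append(
            tuple(
                hashlib.sha256((work / run / f).read_bytes()).hexdigest()
                for f in outputs
                if (work / run / f).exists()
            )
        )
    identical = digests[0] == digests[1] and len(digests[0]) == len(outputs)
    return {"identical": float(identical), "n": len(outputs)}
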