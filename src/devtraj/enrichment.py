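"""Early/late differential expression, cell-type markers, and gene-set
over-representation.

Differential expression uses Welch's unequal-variance t-test on log2
values with Benjamini-Hochberg adjustment; a gene is called only if it
clears both the FDR threshold and the linear fold-change gate
(|log2 FC| > log2 fc_cut).  Cell-type markers are genes expressed at least
``fold`` times higher in one cell type than in every other type.
Gene-set enrichment is the one-sided (over-representation) Fisher exact
test with BH correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, ExpressionDataset, GeneSetCollection
from .simulate import CellTypeMeans

_EPS = 1e-9


@dataclass
class DEGResult:
    """Per-gene differential-expression table plus the decision thresholds.

    The table is indexed by gene with columns ``log2fc`` (late - early),
    ``fold_change`` (direction-signed linear FC), ``pvalue``, ``fdr`` and
    ``direction`` in {up_late, up_early, ns}.
    """

    table: pd.DataFrame
    fdr_cut: float = 0.05
    fc_cut: float = 1.5

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    def genes(self, direction: str) -> list[str]:
        return self.table.index[self.table["direction"] == direction].tolist()


@dataclass
class EnrichmentResult:
    """Per-set over-representation table (k, sizes, odds ratio, p, fdr)."""

    table: pd.DataFrame
    n_query: int
    n_universe: int


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(
    early: ExpressionDataset,
    late: ExpressionDataset,
    fdr_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> DEGResult:
    """Welch's t-test per gene between the early and late stage, on log2 values."""
    if early.gene_ids != late.gene_ids:
        raise DataError("early and late datasets must share the same gene list")
    if early.scale not in ("log2", "log2z") or late.scale not in ("log2", "log2z"):
        raise DataError("differential expression expects log2-scale values")
    if early.n_samples < 2 or late.n_samples < 2:
        raise DataError("need at least 2 samples per side")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(late.values, early.values, axis=1, equal_var=False)
    pvalues = np.asarray(res.pvalue, dtype=float)
    log2fc = late.values.mean(axis=1) - early.values.mean(axis=1)
    # zero-variance degenerate rows: identical groups -> 1, separated -> 0
    bad = ~np.isfinite(pvalues)
    pvalues[bad] = np.where(np.isclose(log2fc[bad], 0.0), 1.0, 0.0)

    fdr = bh_adjust(pvalues)
    fold = np.sign(log2fc) * 2.0 ** np.abs(log2fc)
    fold[log2fc == 0] = 1.0
    called = (fdr < fdr_cut) & (np.abs(fold) > fc_cut)
    direction = np.where(~called, "ns", np.where(log2fc > 0, "up_late", "up_early"))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fold,
            "pvalue": pvalues,
            "fdr": fdr,
            "direction": direction,
        },
        index=pd.Index(early.gene_ids, name="gene"),
    )
    return DEGResult(table=table, fdr_cut=fdr_cut, fc_cut=fc_cut)


def select_markers(means: CellTypeMeans, fold: float = 5.0) -> GeneSetCollection:
    """Genes expressed at least ``fold`` times higher in one cell type than
    in all other cell types.

    A gene expressed in exactly one type (zero elsewhere) is a marker of
    that type; all-zero genes are not markers.
    """
    if len(means.cell_types) < 2:
        raise DataError("need at least two cell types")
    vals = means.values
    sets: dict[str, list[str]] = {ct: [] for ct in means.cell_types}
    top = np.argmax(vals, axis=0)
    for j, g in enumerate(means.gene_ids):
        c = top[j]
        own = vals[c, j]
        if own <= 0:
            continue
        others = np.delete(vals[:, j], c)
        if own + _EPS >= fold * others.max():
            sets[means.cell_types[c]].append(g)
    return GeneSetCollection(
        sets={ct: g for ct, g in sets.items() if g}, universe=list(means.gene_ids)
    )


def overrep_pvalue(k: int, n_query: int, n_set: int, n_universe: int) -> float:
    """One-sided over-representation p-value: P(X >= k) for X hypergeometric
    with ``n_universe`` balls, ``n_set`` white, ``n_query`` drawn."""
    if not 0 <= k <= min(n_query, n_set):
        raise DataError("inconsistent 2x2 table counts")
    return float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_query))


def fisher_enrichment(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> EnrichmentResult:
    """Over-representation of ``query`` in each gene set, BH-corrected.

    Sets are intersected with the universe first; the odds ratio uses the
    Haldane half-count correction whenever a table cell is zero.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise DataError("empty universe")
    uniset = set(uni)
    qset = set(query)
    if not qset <= uniset:
        raise DataError("query must be a subset of the universe")
    n, nq = len(uni), len(qset)
    rows = []
    for name, members in sets.sets.items():
        mem = set(members) & uniset
        if not mem:
            continue
        k = len(qset & mem)
        ns = len(mem)
        p = overrep_pvalue(k, nq, ns, n)
        a, b = k, nq - k
        c, d = ns - k, n - ns - nq + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((name, k, nq, ns, n, (a * d) / (b * c), p))
    table = pd.DataFrame(
        rows,
        columns=["set", "k", "n_query", "n_set", "n_universe", "odds_ratio", "pvalue"],
    ).set_index("set")
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, n_query=nq, n_universe=n)
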