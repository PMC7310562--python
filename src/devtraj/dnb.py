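"""Dynamic network biomarker (DNB) critical-transition detection.

A system approaching a critical transition shows a dominant group of genes
whose internal fluctuation (SD_d) and internal correlation (PCC_d, absolute
Pearson) rise sharply while their correlation with the rest of the
transcriptome (PCC_o) falls.  The composite index

    CI = SD_d * PCC_d / PCC_o

is computed over sliding age windows; the window where CI peaks marks the
transition phase, and the dominant group at that window is the DNB.

The input must be globally z-scored per gene (across all samples), so that
within-window standard deviation genuinely measures local fluctuation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import DataError, ExpressionDataset, SampleMeta


@dataclass
class DNBWindowScore:
    """Scores of the dominant group in one sliding window."""

    window_index: int
    center_age_pcd: float
    member_genes: list[str]
    SD_d: float
    PCC_d: float
    PCC_o: float
    CI: float
    ci_infinite: bool = False  # PCC_o was zero


@dataclass
class DNBResult:
    window_scores: list[DNBWindowScore]
    peak_window: int
    transition_age_pcd: float
    dnb_genes: list[str]
    transition_called: bool  # peak CI clears the significance heuristic
    peak_to_median_ratio: float


def sliding_windows(
    samples: list[SampleMeta], width: int, step: int = 1
) -> list[tuple[list[int], float]]:
    """Overlapping sample-index windows over the age-sorted series.

    Returns ``(indices, center_age)`` pairs; the center age is the median
    age of the window's samples.  Input must already be sorted by age.
    """
    ages = np.array([s.age_pcd for s in samples])
    if np.any(np.diff(ages) < 0):
        raise DataError("samples must be sorted by age")
    n = len(samples)
    if width < 3:
        raise DataError("window width must be >= 3 samples")
    if width > n:
        raise DataError(f"window width {width} exceeds sample count {n}")
    if step < 1:
        raise DataError("step must be >= 1")
    starts = list(range(0, n - width + 1, step))
    if starts[-1] != n - width:  # make sure the final ages are covered
        starts.append(n - width)
    return [
        (list(range(s, s + width)), float(np.median(ages[s : s + width])))
        for s in starts
    ]


def _abs_corr(window_expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson| matrix of the window's rows plus a validity mask.

    Constant rows yield undefined correlations; they are masked out rather
    than propagated as NaN.
    """
    sd = window_expr.std(axis=1)
    valid = sd > 1e-12
    corr = np.zeros((window_expr.shape[0],) * 2)
    if valid.sum() >= 2:
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(window_expr[valid])
        corr[np.ix_(valid, valid)] = np.abs(np.nan_to_num(sub, nan=0.0))
    return corr, valid


def candidate_groups(
    window_expr: np.ndarray,
    min_size: int = 5,
    corr_cut: float = 0.75,
    _cached: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Candidate dominant groups within one window.

    Genes are clustered on distance 1 - |PCC| (average linkage) and the tree
    is cut at height ``1 - corr_cut``.  Each flat cluster is then tightened
    by iteratively dropping the member with the lowest mean |PCC| to the
    rest of the cluster until every member's mean |PCC| reaches
    ``corr_cut`` (average-linkage chaining otherwise attaches weakly
    correlated genes when windows are short).  Clusters of at least
    ``min_size`` genes are returned as row-index arrays; zero-variance
    genes cannot join a group.
    """
    corr, valid = _cached if _cached is not None else _abs_corr(
        np.asarray(window_expr, dtype=float)
    )
    idx = np.flatnonzero(valid)
    if idx.size < min_size:
        return []
    dist = 1.0 - corr[np.ix_(idx, idx)]
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(np.maximum(dist, 0.0), checks=False), method="average")
    flat = fcluster(z, t=1.0 - corr_cut, criterion="distance")
    groups = []
    for label in np.unique(flat):
        members = idx[flat == label]
        while members.size >= min_size:
            sub = corr[np.ix_(members, members)]
            mean_r = (sub.sum(axis=1) - 1.0) / (members.size - 1)
            weakest = int(np.argmin(mean_r))
            if mean_r[weakest] >= corr_cut:
                break
            members = np.delete(members, weakest)
        if members.size >= min_size:
            groups.append(members)
    return groups


def composite_index(
    window_expr: np.ndarray,
    group: np.ndarray,
    window_index: int = 0,
    center_age_pcd: float = float("nan"),
    gene_ids: list[str] | None = None,
    _cached: tuple[np.ndarray, np.ndarray] | None = None,
) -> DNBWindowScore:
    """Score one candidate group in one window.

    SD_d = mean within-window standard deviation of the group genes;
    PCC_d = mean |PCC| over all within-group pairs; PCC_o = mean |PCC| over
    all (group, non-group) pairs; CI = SD_d * PCC_d / PCC_o.  A zero PCC_o
    is flagged and reported as +inf rather than NaN; constant genes are
    excluded from the correlation averages with a warning.
    """
    window_expr = np.asarray(window_expr, dtype=float)
    group = np.asarray(group, dtype=int)
    n_genes = window_expr.shape[0]
    if group.size < 2:
        raise DataError("dominant group needs at least 2 genes")
    if group.size >= n_genes:
        raise DataError("need at least one gene outside the group")
    corr, valid = _cached if _cached is not None else _abs_corr(window_expr)
    if not valid[group].all():
        warnings.warn("constant gene inside group; its pairwise PCCs are excluded", stacklevel=2)

    sds = window_expr.std(axis=1, ddof=1)
    sd_d = float(sds[group].mean())

    in_group = np.zeros(n_genes, dtype=bool)
    in_group[group] = True
    out = ~in_group
    gv = in_group & valid
    ov = out & valid

    pcc_d = 0.0
    if gv.sum() >= 2:
        sub = corr[np.ix_(np.flatnonzero(gv), np.flatnonzero(gv))]
        iu = np.triu_indices(sub.shape[0], k=1)
        pcc_d = float(sub[iu].mean())
    pcc_o = 0.0
    if gv.sum() >= 1 and ov.sum() >= 1:
        pcc_o = float(corr[np.ix_(np.flatnonzero(gv), np.flatnonzero(ov))].mean())

    infinite = pcc_o <= 0.0
    ci = math.inf if infinite else sd_d * pcc_d / pcc_o
    members = (
        [gene_ids[i] for i in group] if gene_ids is not None else [str(i) for i in group]
    )
    return DNBWindowScore(
        window_index=window_index,
        center_age_pcd=center_age_pcd,
        member_genes=members,
        SD_d=sd_d,
        PCC_d=pcc_d,
        PCC_o=pcc_o,
        CI=ci,
        ci_infinite=infinite,
    )


def detect_transition(
    ds: ExpressionDataset,
    width: int = 4,
    step: int = 1,
    min_size: int = 5,
    corr_cut: float = 0.75,
    peak_factor: float = 2.0,
    sd_ratio: float = 1.5,
) -> DNBResult:
    """Scan sliding windows for the CI peak and the DNB gene group.

    The dataset should be globally z-scored per gene (``log2_z_transform``).
    Each window's dominant group is the max-CI candidate group; the peak
    window maximizes CI across windows.  The peak must exceed
    ``peak_factor`` times the median window CI to call a transition
    (otherwise the result is flagged as no-transition).

    The reported DNB membership applies the fluctuation criterion to the
    peak group: a member is kept only when its standard deviation in the
    peak window is at least ``sd_ratio`` times its median window standard
    deviation (genes that merely align with the group's correlation
    pattern in a short window, without elevated deviation, are not DNB
    members).  The refinement is skipped when it would shrink the group
    below ``min_size``.
    """
    ds = ds.sorted_by_age()
    windows = sliding_windows(ds.samples, width=width, step=step)
    scores: list[DNBWindowScore] = []
    for wi, (cols, center) in enumerate(windows):
        expr = ds.values[:, cols]
        cached = _abs_corr(expr)
        best: DNBWindowScore | None = None
        for group in candidate_groups(
            expr, min_size=min_size, corr_cut=corr_cut, _cached=cached
        ):
            score = composite_index(expr, group, wi, center, ds.gene_ids, _cached=cached)
            if best is None or score.CI > best.CI:
                best = score
        if best is None:
            best = DNBWindowScore(wi, center, [], 0.0, 0.0, 0.0, 0.0)
        scores.append(best)

    cis = np.array([s.CI for s in scores])
    finite = np.where(np.isfinite(cis), cis, np.nanmax(np.where(np.isfinite(cis), cis, 0.0)) * 10 + 1)
    peak = int(np.argmax(finite))
    median_ci = float(np.median(finite))
    ratio = math.inf if median_ci == 0 else float(finite[peak] / median_ci)
    called = bool(scores[peak].member_genes) and ratio >= peak_factor

    dnb_genes = list(scores[peak].member_genes)
    if dnb_genes:
        gene_index = {g: i for i, g in enumerate(ds.gene_ids)}
        rows = np.array([gene_index[g] for g in dnb_genes])
        window_sds = np.stack(
            [ds.values[np.ix_(rows, cols)].std(axis=1, ddof=1) for cols, _ in windows],
            axis=1,
        )  # (members, windows)
        typical = np.median(window_sds, axis=1)
        elevated = window_sds[:, peak] >= sd_ratio * np.maximum(typical, 1e-12)
        if elevated.sum() >= min_size:
            dnb_genes = [g for g, keep in zip(dnb_genes, elevated) if keep]

    return DNBResult(
        window_scores=scores,
        peak_window=peak,
        transition_age_pcd=scores[peak].center_age_pcd,
        dnb_genes=dnb_genes,
        transition_called=called,
        peak_to_median_ratio=ratio,
    )
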