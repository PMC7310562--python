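"""Two-stage demarcation of a developmental series by sample clustering.

Samples (columns) are clustered into two groups by agglomerative
hierarchical clustering on correlation distance between their expression
profiles.  The demarcation is then read off the age axis: the single age
cut that best explains the two cluster labels, reported as the interval
(last early age, first late age) together with a purity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import DataError, ExpressionDataset, SampleMeta

LINKAGES = ("average", "complete")


@dataclass
class DemarcationResult:
    """Outcome of demarcation estimation for one linkage method."""

    linkage: str
    labels: dict[str, int]  # sample_id -> cluster in {1, 2}
    demarcation_interval: tuple[float, float]  # (last early age, first late age)
    purity: float  # fraction of samples consistent with the best single age cut
    consistent: bool = True  # both linkage methods agree on the interval
    reliable: bool = True  # purity above threshold

    def __post_init__(self) -> None:
        lo, hi = self.demarcation_interval
        if lo > hi:
            raise ValueError("demarcation interval lower bound exceeds upper bound")


def cluster_samples(ds: ExpressionDataset, linkage_method: str = "average") -> dict[str, int]:
    """Cut the sample dendrogram into exactly two clusters.

    Distance is 1 - Pearson correlation between sample expression profiles;
    the input is expected to be log2-z-transformed.
    """
    if linkage_method not in LINKAGES:
        raise DataError(f"linkage must be one of {LINKAGES}")
    if ds.n_samples < 4:
        raise DataError("need at least 4 samples to cluster")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ds.values.T)
    dist = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(0.0, (dist + dist.T) / 2.0)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(z, t=2, criterion="maxclust")
    return dict(zip(ds.sample_ids, (int(v) for v in labels)))


def estimate_demarcation(
    labels: dict[str, int],
    samples: list[SampleMeta],
    linkage_method: str = "average",
    min_purity: float = 0.75,
) -> DemarcationResult:
    """Turn a 2-cluster labelling into an age-cut demarcation interval.

    Samples are ordered by age and every cut between two distinct adjacent
    ages is scored by its label disagreement (the better of the two
    early/late orientations of the cluster labels; replicates at one age
    cannot be separated, so replicate splits count as disagreements).  The
    minimum-disagreement cut wins; ties go to the earliest cut.
    """
    lab = np.array([labels[s.sample_id] for s in samples])
    if len(set(lab.tolist())) != 2:
        raise DataError("degenerate labelling: need exactly two non-empty clusters")
    ages = np.array([s.age_pcd for s in samples])
    order = np.argsort(ages, kind="stable")
    ages, lab = ages[order], lab[order]
    distinct = np.unique(ages)
    if distinct.size < 2:
        raise DataError("all samples share one age; no cut possible")

    n = ages.size
    best = None  # (disagreements, cut_index)
    for ci in range(distinct.size - 1):
        early = ages <= distinct[ci]
        # orientation A: cluster 1 = early; orientation B: cluster 2 = early
        dis_a = int(np.sum((lab == 2) & early) + np.sum((lab == 1) & ~early))
        dis = min(dis_a, n - dis_a)
        if best is None or dis < best[0]:
            best = (dis, ci)
    disagreements, ci = best
    interval = (float(distinct[ci]), float(distinct[ci + 1]))
    purity = 1.0 - disagreements / n
    return DemarcationResult(
        linkage=linkage_method,
        labels=labels,
        demarcation_interval=interval,
        purity=purity,
        reliable=purity >= min_purity,
    )


def demarcate(
    ds: ExpressionDataset,
    linkages: tuple[str, ...] = LINKAGES,
    min_purity: float = 0.75,
) -> list[DemarcationResult]:
    """Run clustering + demarcation for each linkage; flag cross-method agreement."""
    results = []
    for method in linkages:
        labels = cluster_samples(ds, method)
        results.append(estimate_demarcation(labels, ds.samples, method, min_purity))
    intervals = {r.demarcation_interval for r in results}
    consistent = len(intervals) == 1
    for r in results:
        r.consistent = consistent
    return results
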