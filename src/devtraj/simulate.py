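"""Synthetic two-species developmental expression data with planted truth.

The generator emulates the structure a comparative developmental
transcriptome study assumes: smooth per-gene trajectories over log2 age, a
two-stage structure created by stage-switch genes whose mean steps at a
species-specific transition age, a dynamic-network-biomarker (DNB) gene
group whose noise becomes strongly correlated and inflated in a window
around the transition, heterochronic genes whose human trajectory is
time-shifted on the log2-age axis, block-correlated co-expression modules
whose connectivity differs between early and late stages, and a cell-type
mean-expression table with fold-change markers.

Everything is driven by a single :class:`SimConfig` and a single seed, and
the planted ground truth is returned as a :class:`SyntheticTruth` so every
downstream stage can be validated without external data.

Signal and noise are generated on the log2 scale (both source platforms in
this field are analysed after log transform) and exponentiated, so the
emitted matrices are linear-scale and flow through the same
filter -> log2 -> z preprocessing as real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ExpressionDataset, SampleMeta

# Default sampling grids follow the study's human/macaque age tables:
# prenatal ages in postconception days, postnatal ages converted to PCD
# with gestation lengths of 266 d (human) and 165 d (macaque).  The human
# postnatal grid is thinned to keep default datasets small.
DEFAULT_AGES_HUMAN = (
    56.0, 72.0, 80.0, 90.0, 120.0, 133.0, 147.0, 168.0, 175.0,  # 8-25 PCW
    182.0,            # 26 PCW
    386.0,            # 4 months
    566.0,            # 10 months
    631.0,            # 1 year
    996.0,            # 2 years
    1726.0,           # 4 years
    3186.0,           # 8 years
    5741.0,           # 15 years
)
DEFAULT_AGES_MACAQUE = (
    50.0, 70.0, 84.0, 91.0, 112.0, 119.0,   # 8-17 PCW
    165.0,            # birth
    255.0,            # 3 months
    530.0,            # 12 months
    1625.0,           # 48 months
)

MODULE_CLASSES = ("gain", "loss", "none")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-species study.

    Effect sizes are on the log2 scale.  ``shift_log2age`` is the planted
    heterochronic time shift in log2-age units (positive = human trajectory
    delayed, i.e. neoteny).
    """

    n_genes: int = 300
    ages_human: tuple[float, ...] = DEFAULT_AGES_HUMAN
    ages_macaque: tuple[float, ...] = DEFAULT_AGES_MACAQUE
    replicates_per_age: int = 2
    transition_age_human: float = 175.0
    transition_age_macaque: float = 119.0
    n_switch: int = 100
    switch_delta: float = 1.0
    n_dnb: int = 20
    dnb_sd_inflation: float = 3.0
    dnb_intra_corr: float = 0.9
    n_neoteny: int = 15
    n_acceleration: int = 10
    shift_log2age: float = 1.0
    n_modules: int = 3
    module_size: int = 30
    module_corr_early: float = 0.7
    module_corr_late: float = 0.2
    n_celltypes: int = 5
    markers_per_type: int = 8
    marker_fold: float = 5.0
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_switch
            + self.n_dnb
            + self.n_neoteny
            + self.n_acceleration
            + self.n_modules * self.module_size
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted roles need {planted} genes but n_genes={self.n_genes}"
            )
        for name in ("dnb_intra_corr", "module_corr_early", "module_corr_late"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.dnb_sd_inflation < 1.0:
            raise ValueError("dnb_sd_inflation must be >= 1")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")
        if self.replicates_per_age < 1:
            raise ValueError("replicates_per_age must be >= 1")
        if min(self.ages_human) <= 0 or min(self.ages_macaque) <= 0:
            raise ValueError("ages must be positive (postconception days)")
        if not (min(self.ages_human) < self.transition_age_human < max(self.ages_human)):
            raise ValueError("transition_age_human outside the human age grid")
        if not (min(self.ages_macaque) < self.transition_age_macaque < max(self.ages_macaque)):
            raise ValueError("transition_age_macaque outside the macaque age grid")
        if self.n_celltypes * self.markers_per_type > self.n_genes - planted:
            raise ValueError("not enough unplanted genes left for cell-type markers")


@dataclass
class CellTypeMeans:
    """Cell-type-by-gene table of mean expression on the linear scale."""

    values: np.ndarray  # (n_celltypes, n_genes)
    cell_types: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("cell-type means must be nonnegative")
        if self.values.shape != (len(self.cell_types), len(self.gene_ids)):
            raise ValueError("cell-type mean table shape mismatch")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_types, columns=self.gene_ids)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset pair."""

    transition_age: dict[str, float]
    dnb_genes: list[str]
    shifts: dict[str, float]  # gene -> signed log2-age shift (positive = human delayed)
    module_blocks: dict[str, tuple[list[str], str]]  # module -> (genes, class)
    module_regulators: dict[str, str]
    markers: dict[str, list[str]]
    switch_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "transition_age": self.transition_age,
            "dnb_genes": self.dnb_genes,
            "shifts": self.shifts,
            "module_blocks": {
                m: {"genes": genes, "class": cls}
                for m, (genes, cls) in self.module_blocks.items()
            },
            "module_regulators": self.module_regulators,
            "markers": self.markers,
            "switch_genes": self.switch_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            transition_age=payload["transition_age"],
            dnb_genes=payload["dnb_genes"],
            shifts=payload["shifts"],
            module_blocks={
                m: (d["genes"], d["class"]) for m, d in payload["module_blocks"].items()
            },
            module_regulators=payload["module_regulators"],
            markers=payload["markers"],
            switch_genes=payload["switch_genes"],
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _sample_grid(ages: tuple[float, ...], replicates: int, prefix: str):
    sample_ages = []
    sample_ids = []
    for a in sorted(ages):
        for r in range(replicates):
            sample_ages.append(a)
            sample_ids.append(f"{prefix}_{a:07.1f}_r{r + 1}")
    return np.array(sample_ages), sample_ids


def _window_age_mask(ages: np.ndarray, grid: np.ndarray, transition: float) -> np.ndarray:
    """Samples whose age lies within one grid step of the transition age."""
    grid = np.sort(np.unique(grid))
    i = int(np.argmin(np.abs(grid - transition)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    return (ages >= lo) & (ages <= hi)


def generate(
    config: SimConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, SyntheticTruth, CellTypeMeans]:
    """Generate the human/macaque dataset pair, truth, and cell-type means.

    Deterministic for a fixed ``config.seed`` (bit-identical reruns).
    """
    return _generate(config, null=False)


def null_dataset(
    config: SimConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, SyntheticTruth, CellTypeMeans]:
    """Same generative machinery with every planted effect zeroed.

    Used for type-I-error / calibration checks: no mean step, no time shift,
    no noise inflation or extra correlation, equal module connectivity in
    both stages, no marker fold change, and flat baselines (a smooth age
    trajectory is itself a real early/late mean difference, so a calibration
    null must not contain one).  The returned truth has empty lists.
    """
    mid_corr = 0.5 * (config.module_corr_early + config.module_corr_late)
    null_cfg = dataclasses.replace(
        config,
        switch_delta=0.0,
        shift_log2age=0.0,
        dnb_sd_inflation=1.0,
        dnb_intra_corr=0.0,
        module_corr_early=mid_corr,
        module_corr_late=mid_corr,
        marker_fold=1.0,
    )
    return _generate(null_cfg, null=True)


def _generate(config: SimConfig, null: bool):
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]

    # --- role assignment (disjoint, deterministic) ----------------------
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    switch_idx = take(config.n_switch)
    dnb_idx = take(config.n_dnb)
    neo_idx = take(config.n_neoteny)
    acc_idx = take(config.n_acceleration)
    module_idx = [take(config.module_size) for _ in range(config.n_modules)]
    marker_idx = [take(config.markers_per_type) for _ in range(config.n_celltypes)]

    # --- sampling grids --------------------------------------------------
    ages_h, ids_h = _sample_grid(config.ages_human, config.replicates_per_age, "H")
    ages_m, ids_m = _sample_grid(config.ages_macaque, config.replicates_per_age, "M")
    u_h, u_m = np.log2(ages_h), np.log2(ages_m)
    grid_u = np.log2(np.unique(np.concatenate([config.ages_human, config.ages_macaque])))
    center, scale = grid_u.mean(), grid_u.std()

    # --- baseline trajectories: cubic polynomials in normalized log2 age --
    c0 = rng.normal(config.baseline_mean, 1.0, size=n)
    coef = np.column_stack(
        [
            rng.normal(0.0, 0.5, size=n),   # linear
            rng.normal(0.0, 0.25, size=n),  # quadratic
            rng.normal(0.0, 0.1, size=n),   # cubic
        ]
    )
    # Stage-switch, DNB and module-block genes are step-like / fluctuation-
    # driven / factor-driven: a flat baseline makes the planted offset
    # (resp. windowed covariance, resp. block correlation) the whole
    # structure of these genes, so each planted effect is exactly the
    # stated effect size rather than being confounded with smooth trends.
    coef[switch_idx, :] = 0.0
    coef[dnb_idx, :] = 0.0
    for block in module_idx:
        coef[block, :] = 0.0
    # Heterochronic genes emulate the post-screen population of strongly
    # age-related genes with rise-and-fall (saturating) trajectories: a
    # guaranteed quadratic component with the vertex inside the sampled
    # range.  A time shift of a near-linear trajectory is equivalent to a
    # vertical offset and therefore carries no timing information; only
    # curved trajectories make heterochrony identifiable.
    hetero_idx = np.concatenate([neo_idx, acc_idx])
    if hetero_idx.size:
        signs = rng.choice([-1.0, 1.0], size=hetero_idx.size)
        a2 = signs * rng.uniform(0.8, 1.5, size=hetero_idx.size)
        vertex = rng.uniform(-0.5, 0.5, size=hetero_idx.size)
        coef[hetero_idx, 0] = -2.0 * a2 * vertex
        coef[hetero_idx, 1] = a2
        coef[hetero_idx, 2] = 0.0
    if null:
        coef[:, :] = 0.0

    # Per-gene log2-age shift: +delta = human delayed (neoteny).
    delta = np.zeros(n)
    delta[neo_idx] = config.shift_log2age
    delta[acc_idx] = -config.shift_log2age

    def signal(u: np.ndarray, shifted: bool) -> np.ndarray:
        # (n_genes, n_samples) smooth means; the human matrix applies the
        # per-gene time shift, the macaque matrix never does.
        d = delta[:, None] if shifted else 0.0
        x = (u[None, :] - d - center) / scale
        return c0[:, None] + coef[:, 0:1] * x + coef[:, 1:2] * x**2 + coef[:, 2:3] * x**3

    sig_h = signal(u_h, shifted=True)
    sig_m = signal(u_m, shifted=False)

    # --- stage-switch offsets (half up, half down) ------------------------
    step_sign = np.where(np.arange(config.n_switch) % 2 == 0, 1.0, -1.0)
    late_h = ages_h > config.transition_age_human
    late_m = ages_m > config.transition_age_macaque
    sig_h[switch_idx[:, None], np.flatnonzero(late_h)[None, :]] += (
        config.switch_delta * step_sign[:, None]
    )
    sig_m[switch_idx[:, None], np.flatnonzero(late_m)[None, :]] += (
        config.switch_delta * step_sign[:, None]
    )

    # --- noise ------------------------------------------------------------
    noise_h = rng.normal(0.0, config.noise_sd, size=sig_h.shape)
    noise_m = rng.normal(0.0, config.noise_sd, size=sig_m.shape)

    def plant_dnb(noise: np.ndarray, ages: np.ndarray, grid, transition: float) -> None:
        # Equicorrelated inflated noise for DNB genes inside a +-1-age-step
        # window around the transition; independent noise elsewhere.
        if config.n_dnb == 0:
            return
        mask = _window_age_mask(ages, np.asarray(grid), transition)
        cols = np.flatnonzero(mask)
        rho = config.dnb_intra_corr
        sd = config.noise_sd * config.dnb_sd_inflation
        shared = rng.normal(0.0, 1.0, size=cols.size)
        own = rng.normal(0.0, 1.0, size=(config.n_dnb, cols.size))
        corr_noise = sd * (np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * own)
        noise[dnb_idx[:, None], cols[None, :]] = corr_noise

    plant_dnb(noise_h, ages_h, config.ages_human, config.transition_age_human)
    plant_dnb(noise_m, ages_m, config.ages_macaque, config.transition_age_macaque)

    # --- module blocks: latent-factor noise, stage-dependent loading ------
    module_names = [f"M{k + 1}" for k in range(config.n_modules)]
    if null:
        module_classes = ["none"] * config.n_modules
    else:
        module_classes = [MODULE_CLASSES[k % 3] for k in range(config.n_modules)]

    def module_corrs(cls: str) -> tuple[float, float]:
        hi, lo = config.module_corr_early, config.module_corr_late
        if cls == "gain":
            return hi, lo
        if cls == "loss":
            return lo, hi
        return 0.5 * (hi + lo), 0.5 * (hi + lo)

    def plant_modules(noise: np.ndarray, ages: np.ndarray, transition: float) -> None:
        early = ages <= transition
        for block, cls in zip(module_idx, module_classes):
            rho_e, rho_l = module_corrs(cls)
            rho = np.where(early, rho_e, rho_l)  # per-sample loading
            factor = rng.normal(0.0, 1.0, size=ages.size)
            own = rng.normal(0.0, 1.0, size=(block.size, ages.size))
            vals = config.noise_sd * (
                np.sqrt(rho)[None, :] * factor[None, :]
                + np.sqrt(1.0 - rho)[None, :] * own
            )
            # First gene of the block is an observed regulator: it emits the
            # factor itself during the early stage and decouples afterwards,
            # making it a planted early-specific hub.
            reg_own = rng.normal(0.0, 1.0, size=ages.size)
            vals[0, :] = config.noise_sd * np.where(early, factor, reg_own)
            noise[block, :] = vals

    plant_modules(noise_h, ages_h, config.transition_age_human)
    plant_modules(noise_m, ages_m, config.transition_age_macaque)

    values_h = 2.0 ** (sig_h + noise_h)
    values_m = 2.0 ** (sig_m + noise_m)

    def dataset(values, ids, ages, species) -> ExpressionDataset:
        samples = [
            SampleMeta(sample_id=i, species=species, region="V1C", age_pcd=float(a))
            for i, a in zip(ids, ages)
        ]
        return ExpressionDataset(values=values, gene_ids=list(genes), samples=samples)

    ds_h = dataset(values_h, ids_h, ages_h, "human")
    ds_m = dataset(values_m, ids_m, ages_m, "macaque")

    # --- cell-type mean table ---------------------------------------------
    cell_types = [f"celltype_{c + 1}" for c in range(config.n_celltypes)]
    base = 2.0 ** rng.normal(6.0, 1.0, size=n)
    means = base[None, :] * rng.uniform(0.8, 1.25, size=(config.n_celltypes, n))
    for c, block in enumerate(marker_idx):
        for g in block:
            others = np.delete(np.arange(config.n_celltypes), c)
            means[others, g] = base[g] * rng.uniform(0.8, 1.0, size=others.size)
            means[c, g] = config.marker_fold * means[others, g].max() * 1.01
    cell_means = CellTypeMeans(values=means, cell_types=cell_types, gene_ids=list(genes))

    # --- truth ------------------------------------------------------------
    gname = np.asarray(genes)
    if null:
        truth = SyntheticTruth(
            transition_age={
                "human": config.transition_age_human,
                "macaque": config.transition_age_macaque,
            },
            dnb_genes=[],
            shifts={},
            module_blocks={},
            module_regulators={},
            markers={},
            switch_genes=[],
        )
    else:
        truth = SyntheticTruth(
            transition_age={
                "human": config.transition_age_human,
                "macaque": config.transition_age_macaque,
            },
            dnb_genes=gname[dnb_idx].tolist(),
            shifts={
                **{g: config.shift_log2age for g in gname[neo_idx]},
                **{g: -config.shift_log2age for g in gname[acc_idx]},
            },
            module_blocks={
                name: (gname[block].tolist(), cls)
                for name, block, cls in zip(module_names, module_idx, module_classes)
            },
            module_regulators={
                name: gname[block[0]].item()
                for name, block in zip(module_names, module_idx)
            },
            markers={
                ct: gname[block].tolist() for ct, block in zip(cell_types, marker_idx)
            },
            switch_genes=gname[switch_idx].tolist(),
        )
    return ds_h, ds_m, truth, cell_means
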