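"""End-to-end orchestration: demarcation -> DNB -> DE/enrichment ->
heterochrony -> networks, with a reproducibility manifest.

Every stage writes plain JSON/TSV into the output directory; the manifest
records the seed, every stage parameter, input checksums and the package
version, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import core, demarcation, dnb, enrichment, heterochrony, network, simulate
from .core import DataError


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run.

    All decision thresholds of the analysis appear here as named defaults
    (expressed-gene fraction 0.8, FDR 0.05, fold change 1.5, screening
    P 0.05, five-fold marker rule) so the fidelity surface is auditable.
    """

    matrix: str
    meta: str
    out_dir: str
    macaque_matrix: str | None = None
    macaque_meta: str | None = None
    gmt: str | None = None
    cell_means: str | None = None
    seed: int = 0
    boundary_pcd: float | None = None  # force the stage boundary; None = detected
    min_expressed_fraction: float = 0.8
    pseudocount: float = 1.0
    dnb_width: int = 4
    dnb_step: int = 1
    dnb_min_size: int = 5
    dnb_corr_cut: float = 0.75
    fdr_cut: float = 0.05
    fc_cut: float = 1.5
    marker_fold: float = 5.0
    hetero_sims: int = 200
    min_module_size: int = 30
    module_cut_height: float = 0.95
    mdc_tau: float = 0.1
    dpi_tolerance: float = 0.15
    key_driver_hops: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def _finite(x: float) -> float | str:
    return x if np.isfinite(x) else ("inf" if x > 0 else "-inf")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns a summary dict (also written as ``summary.json``).  Stage
    failures raise with a stage-tagged message; outputs of completed stages
    are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # re-tag for diagnosis
                raise RuntimeError(f"[stage {name}] {exc}") from exc

        return wrap

    # -- load & preprocess -------------------------------------------------
    def _load():
        ds = core.load_expression(config.matrix, config.meta)
        ds = core.filter_expressed(ds, config.min_expressed_fraction)
        log2 = core.log2_transform(ds, config.pseudocount)
        z = core.log2_z_transform(ds, config.pseudocount)
        return ds, log2, z

    ds, ds_log2, ds_z = stage("load")(_load)

    # -- demarcation -------------------------------------------------------
    def _demarcate():
        results = demarcation.demarcate(ds_z)
        payload = [
            {
                "linkage": r.linkage,
                "interval_pcd": list(r.demarcation_interval),
                "purity": r.purity,
                "consistent": r.consistent,
                "reliable": r.reliable,
            }
            for r in results
        ]
        _dump_json(payload, out / "demarcation.json")
        return results

    dem = stage("demarcation")(_demarcate)
    boundary = (
        config.boundary_pcd
        if config.boundary_pcd is not None
        else dem[0].demarcation_interval[0]
    )
    summary["boundary_pcd"] = boundary

    # -- DNB ---------------------------------------------------------------
    def _dnb():
        res = dnb.detect_transition(
            ds_z,
            width=config.dnb_width,
            step=config.dnb_step,
            min_size=config.dnb_min_size,
            corr_cut=config.dnb_corr_cut,
        )
        payload = {
            "transition_age_pcd": res.transition_age_pcd,
            "transition_called": res.transition_called,
            "peak_window": res.peak_window,
            "peak_to_median_ratio": _finite(res.peak_to_median_ratio),
            "dnb_genes": res.dnb_genes,
            "windows": [
                {
                    "index": w.window_index,
                    "center_age_pcd": w.center_age_pcd,
                    "SD_d": w.SD_d,
                    "PCC_d": w.PCC_d,
                    "PCC_o": w.PCC_o,
                    "CI": _finite(w.CI),
                    "n_members": len(w.member_genes),
                }
                for w in res.window_scores
            ],
        }
        _dump_json(payload, out / "dnb.json")
        return res

    dnb_res = stage("dnb")(_dnb)
    summary["dnb_transition_age_pcd"] = dnb_res.transition_age_pcd
    summary["n_dnb_genes"] = len(dnb_res.dnb_genes)

    # -- differential expression + enrichment ------------------------------
    def _de():
        early, late = core.split_by_age(ds_log2, boundary)
        degs = enrichment.differential_expression(
            early, late, config.fdr_cut, config.fc_cut
        )
        degs.table.to_csv(out / "degs.tsv", sep="\t", float_format="%.6g")
        universe = list(degs.table.index)
        enr_payload = {}
        query = degs.significant().index.tolist()
        gene_sets = None
        if config.gmt:
            gene_sets = core.read_gmt(config.gmt)
        if config.cell_means:
            cm = load_cell_means(config.cell_means)
            markers = enrichment.select_markers(cm, config.marker_fold)
            if gene_sets is None:
                gene_sets = markers
            else:
                gene_sets = core.GeneSetCollection(
                    sets={**gene_sets.sets, **markers.sets}
                )
        if gene_sets is not None and query:
            enr = enrichment.fisher_enrichment(query, gene_sets, universe)
            enr.table.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
            enr_payload = {"n_sets": len(enr.table)}
        return degs, enr_payload

    degs, enr_payload = stage("differential_expression")(_de)
    summary["n_degs"] = int((degs.table["direction"] != "ns").sum())
    summary.update(enr_payload)

    # -- heterochrony (needs the second species) ---------------------------
    if config.macaque_matrix and config.macaque_meta:

        def _hetero():
            ds_m = core.load_expression(config.macaque_matrix, config.macaque_meta)
            ds_m = core.filter_expressed(ds_m, config.min_expressed_fraction)
            shared = [g for g in ds.gene_ids if g in set(ds_m.gene_ids)]
            h_log2 = core.log2_transform(ds.subset_genes(shared), config.pseudocount)
            m_log2 = core.log2_transform(ds_m.subset_genes(shared), config.pseudocount)
            screens, calls = heterochrony.call_heterochrony(
                h_log2, m_log2, n_sims=config.hetero_sims, seed=config.seed
            )
            lines = ["gene\tage_pvalue\tspecies_pvalue\tshift_log2age\tshift_pvalue\tclass"]
            by_gene = {c.gene: c for c in calls}
            for sc in screens:
                c = by_gene.get(sc.gene)
                lines.append(
                    "\t".join(
                        [
                            sc.gene,
                            f"{sc.age_pvalue:.6g}",
                            f"{sc.species_pvalue:.6g}",
                            f"{c.shift_log2age:.6g}" if c else "",
                            f"{c.shift_pvalue:.6g}" if c else "",
                            c.klass if c else "not_tested",
                        ]
                    )
                )
            (out / "heterochrony.tsv").write_text("\n".join(lines) + "\n")
            return calls

        calls = stage("heterochrony")(_hetero)
        summary["n_neoteny"] = sum(c.klass == "neoteny" for c in calls)
        summary["n_acceleration"] = sum(c.klass == "acceleration" for c in calls)

    # -- networks ----------------------------------------------------------
    def _network():
        early_z, late_z = core.split_by_age(ds_z, boundary)
        modules = network.build_modules(
            early_z, config.min_module_size, config.module_cut_height
        )
        network.score_modules(modules, early_z, late_z, config.mdc_tau)
        payload = {
            "soft_power": modules.soft_power,
            "modules": {
                str(mid): {
                    "genes": genes,
                    "mdc": _finite(modules.module_mdc[mid][0]),
                    "class": modules.module_mdc[mid][1],
                }
                for mid, genes in sorted(modules.modules().items())
            },
        }
        _dump_json(payload, out / "modules.json")

        drivers_payload = {}
        mods = modules.modules()
        if mods:
            # key-driver analysis of the top gain module (fall back to the
            # largest module when none gains connectivity)
            gains = [
                (modules.module_mdc[m][0], m)
                for m in mods
                if modules.module_mdc[m][1] == "gain"
            ]
            target = max(gains)[1] if gains else max(mods, key=lambda m: len(mods[m]))
            genes = mods[target]
            e_net = network.mi_network(
                early_z.subset_genes(genes).values, genes,
                dpi_tolerance=config.dpi_tolerance, seed=config.seed,
            )
            l_net = network.mi_network(
                late_z.subset_genes(genes).values, genes,
                dpi_tolerance=config.dpi_tolerance, seed=config.seed + 1,
            )
            hubs = network.key_drivers(e_net, hops=config.key_driver_hops)
            esh = network.early_specific_hubs(e_net, l_net, hops=config.key_driver_hops)
            drivers_payload = {
                "module": int(target),
                "hubs": hubs,
                "early_specific_hubs": esh,
                "n_edges_early": e_net.graph.number_of_edges(),
                "n_edges_late": l_net.graph.number_of_edges(),
            }
            _dump_json(drivers_payload, out / "key_drivers.json")
        return modules, drivers_payload

    modules, drivers_payload = stage("network")(_network)
    summary["n_modules"] = len(modules.modules())
    summary["n_hubs"] = len(drivers_payload.get("hubs", []))

    # -- manifest ----------------------------------------------------------
    inputs = {
        name: _sha256(path)
        for name, path in (
            ("matrix", config.matrix),
            ("meta", config.meta),
            ("macaque_matrix", config.macaque_matrix),
            ("macaque_meta", config.macaque_meta),
            ("gmt", config.gmt),
            ("cell_means", config.cell_means),
        )
        if path
    }
    manifest = {
        "devtraj_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "input_sha256": inputs,
    }
    _dump_json(manifest, out / "manifest.json")
    _dump_json(summary, out / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# demo bundle
# ---------------------------------------------------------------------------


def load_cell_means(path: str | Path) -> simulate.CellTypeMeans:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return simulate.CellTypeMeans(
        values=frame.to_numpy(dtype=float),
        cell_types=[str(c) for c in frame.index],
        gene_ids=[str(g) for g in frame.columns],
    )


def make_demo(seed: int, out_dir: str | Path, config: simulate.SimConfig | None = None) -> dict:
    """Write a complete synthetic input bundle (matrices, metadata, truth,
    cell-type means, marker GMT) for walkthroughs and pipeline runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config or simulate.SimConfig(), seed=seed)
    ds_h, ds_m, truth, cell_means = simulate.generate(cfg)
    core.write_expression(ds_h, out / "human_matrix.tsv", out / "human_meta.tsv")
    core.write_expression(ds_m, out / "macaque_matrix.tsv", out / "macaque_meta.tsv")
    truth.to_json(out / "truth.json")
    cell_means.to_frame().to_csv(out / "cell_means.tsv", sep="\t", float_format="%.10g")
    if truth.markers:
        core.write_gmt(
            core.GeneSetCollection(sets=dict(truth.markers)),
            out / "marker_sets.gmt",
            description="planted cell-type markers",
        )
    return {
        "human_matrix": str(out / "human_matrix.tsv"),
        "human_meta": str(out / "human_meta.tsv"),
        "macaque_matrix": str(out / "macaque_matrix.tsv"),
        "macaque_meta": str(out / "macaque_meta.tsv"),
        "truth": str(out / "truth.json"),
        "cell_means": str(out / "cell_means.tsv"),
    }
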