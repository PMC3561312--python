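"""One-shot end-to-end runs: configuration, orchestration, machine-readable report.

A run takes two or more site datasets (loaded from files or simulated),
gene/CpG/CNC annotation and optional tag tracks, then emits a Table-1-style
class summary, TSS/CpG/CNC distance profiles, tag-density profiles, cluster
sets with numerosity-adjusted windows, pairwise cluster-overlap fractions
and pairwise Fisher comparisons, plus a JSON manifest of parameters and
seeds. Reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as isio
from .annotate import annotate_dataset, midpoint_distance_profile, tss_distance_profile
from .clustering import (
    DEFAULT_EFFECTIVE_GENOME,
    ClusterParams,
    calibrate_window,
    call_clusters,
    overlap_clusters,
)
from .profiles import tag_density_profile
from .simulate import BiasModel, make_genome, simulate_sites, simulate_tags
from .stats import class_extractor, compare_category, feature_association_extractor, random_control


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the published analysis settings."""

    outdir: str = "intsite_out"
    seed: int = 0
    tss_halfwidth: int = 2500
    assoc_halfwidth: int = 1000
    profile_window: int = 50000
    profile_bin: int = 2500
    fine_bin: int = 50
    tag_window: int = 5000
    tag_bin: int = 50
    n_min: int = 3
    alpha: float = 0.01
    g_eff: int = DEFAULT_EFFECTIVE_GENOME
    min_len: int = 20
    min_identity: float = 0.95
    tolerance: int = 3
    min_overlap: int = 1
    # inputs: either paths ...
    site_paths: dict = field(default_factory=dict)  # name -> path (TSV)
    genes_path: str | None = None
    cpg_path: str | None = None
    cnc_path: str | None = None
    tag_paths: dict = field(default_factory=dict)  # name -> path (BED)
    # ... or a simulation scenario
    simulate: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def demo_config(outdir: str = "intsite_demo", seed: int = 0, n_sites: int = 3000) -> RunConfig:
    """Two same-bias MLV-like datasets on a synthetic genome (the demo scenario).

    The genome/site ratio is chosen so the calibrated cluster window is
    comparable to the ±2.5-kb placement kernel — the regime in which two
    datasets drawn from one bias model form clusters at shared anchors,
    as the real paired datasets do.
    """
    return RunConfig(
        outdir=outdir,
        seed=seed,
        g_eff=0,  # use the synthetic genome's own size
        simulate={
            "n_chrom": 2,
            "mean_length": 25_000_000,
            "n_genes": 150,
            "n_cpg": 100,
            "n_cnc": 80,
            "datasets": [
                {"name": "SIN-like", "n_sites": n_sites, "bias": "mlv_like"},
                {"name": "LTR-like", "n_sites": n_sites, "bias": "mlv_like"},
            ],
            "random_control": n_sites,
            "tags": {"promoter_mark": {"n_tags": 30000, "enriched_fraction": 0.6, "decay_halfwidth": 1000}},
        },
    )


def _build_inputs(config: RunConfig):
    if config.simulate is not None:
        sc = config.simulate
        genome, genes, cpg, cnc = make_genome(
            sc["n_chrom"], sc["mean_length"], sc["n_genes"], sc.get("n_cpg", 0), sc.get("n_cnc", 0),
            seed=config.seed,
        )
        datasets = []
        for k, entry in enumerate(sc["datasets"]):
            bias = BiasModel.mlv_like() if entry.get("bias", "uniform") == "mlv_like" else BiasModel.uniform()
            datasets.append(
                simulate_sites(genome, genes, cpg, entry["n_sites"], bias,
                               seed=config.seed + 1000 * (k + 1), name=entry["name"])
            )
        if sc.get("random_control"):
            datasets.append(random_control(genome, sc["random_control"], seed=config.seed + 99, name="random"))
        tags = {}
        anchors = [(c, int(p)) for c, p in zip(genes.df["chrom"], genes.tss)]
        for j, (name, tspec) in enumerate(sorted(sc.get("tags", {}).items())):
            tags[name] = simulate_tags(
                genome, anchors, tspec["n_tags"], tspec["enriched_fraction"], tspec["decay_halfwidth"],
                seed=config.seed + 7 * (j + 1), name=name,
            )
        return genome, genes, cpg, cnc, datasets, tags
    if not config.site_paths or config.genes_path is None:
        raise ValueError("config needs either a simulate scenario or site/gene input paths")
    datasets = [isio.read_sites(p, "tsv", name=n) for n, p in config.site_paths.items()]
    genes = isio.read_genes(config.genes_path)
    cpg = isio.read_features(config.cpg_path, "CpG") if config.cpg_path else None
    cnc = isio.read_features(config.cnc_path, "CNC") if config.cnc_path else None
    tags = {n: isio.read_tags(p, name=n) for n, p in config.tag_paths.items()}
    if cpg is None or cnc is None:
        from .genome import FeatureTrack

        cpg = cpg or FeatureTrack("CpG")
        cnc = cnc or FeatureTrack("CNC")
    return None, genes, cpg, cnc, datasets, tags


def run_all(config: RunConfig) -> dict:
    """Run every stage and write TSV/BED/JSON outputs under ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    genome, genes, cpg, cnc, datasets, tags = _build_inputs(config)
    g_eff = config.g_eff if config.g_eff else (genome.total_length if genome else DEFAULT_EFFECTIVE_GENOME)
    report: dict = {"parameters": {**asdict(config), "g_eff_used": g_eff}}

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with _stage("annotate"):
        rows = []
        annotations = {}
        for ds in datasets:
            res = annotate_dataset(ds, genes, cpg, cnc, config.tss_halfwidth, config.assoc_halfwidth)
            annotations[ds.name] = res
            rows.append(res.as_row())
        table1 = pd.DataFrame(rows)
        table1.to_csv(os.path.join(config.outdir, "class_summary.tsv"), sep="\t", index=False)
        report["class_summary"] = rows

    with _stage("profiles"):
        for ds in datasets:
            prof = tss_distance_profile(ds, genes, config.profile_window, config.profile_bin)
            prof.to_frame().to_csv(os.path.join(config.outdir, f"tss_profile_{ds.name}.tsv"), sep="\t", index=False)
            for track in (cpg, cnc):
                if len(track):
                    mp = midpoint_distance_profile(ds, track, config.profile_window, config.profile_bin)
                    mp.to_frame().to_csv(
                        os.path.join(config.outdir, f"{track.name}_profile_{ds.name}.tsv"), sep="\t", index=False
                    )

    with _stage("tag_profiles"):
        for tname, track in tags.items():
            for ds in datasets:
                mat = tag_density_profile(ds, track, config.tag_window, config.tag_bin)
                mat.to_frame().to_csv(
                    os.path.join(config.outdir, f"tagdensity_{tname}_{ds.name}.tsv"), sep="\t", index=False
                )

    with _stage("clusters"):
        cluster_sets = {}
        for ds in datasets:
            w = calibrate_window(ds.n, g_eff, config.n_min, config.alpha)
            params = ClusterParams(config.n_min, config.alpha, g_eff, w)
            cs = call_clusters(ds, params)
            cluster_sets[ds.name] = cs
            isio.write_clusters(cs, os.path.join(config.outdir, f"clusters_{ds.name}.bed"))
        report["clusters"] = {name: cs.summary() for name, cs in cluster_sets.items()}

    with _stage("overlap"):
        overlaps = {}
        names = [ds.name for ds in datasets]
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                f1, _ = overlap_clusters(cluster_sets[na], cluster_sets[nb], 1)
                fk, _ = overlap_clusters(cluster_sets[na], cluster_sets[nb], 1000)
                overlaps[f"{na}|{nb}"] = {"min1bp": f1, "min1kb": fk}
        report["cluster_overlap"] = overlaps

    with _stage("fisher"):
        comparisons = []
        extractors = {
            "TSS_proximal": class_extractor(genes, "TSS_proximal", config.tss_halfwidth),
            "intragenic": class_extractor(genes, "intragenic", config.tss_halfwidth),
            "intergenic": class_extractor(genes, "intergenic", config.tss_halfwidth),
        }
        if len(cpg):
            extractors["cpg"] = feature_association_extractor(cpg, config.assoc_halfwidth)
        if len(cnc):
            extractors["cnc"] = feature_association_extractor(cnc, config.assoc_halfwidth)
        names = [ds.name for ds in datasets]
        by_name = {ds.name: ds for ds in datasets}
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                for cat, ext in extractors.items():
                    cmp_res = compare_category(by_name[na], by_name[nb], ext)
                    comparisons.append({"pair": f"{na}|{nb}", "category": cat, **cmp_res.as_dict()})
        pd.DataFrame(comparisons).to_csv(os.path.join(config.outdir, "fisher_comparisons.tsv"), sep="\t", index=False)
        report["fisher"] = comparisons

    report["manifest"] = {"seed": config.seed, "n_datasets": len(datasets), "datasets": {d.name: d.n for d in datasets}}
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
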