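"""End-to-end orchestration: simulate -> normalize -> classify ->
stochasticity -> co-expression -> spike-in scaling, with a JSON manifest.

Every stage is deterministic under the configured master seed; the manifest
records the configuration hash, seeds and per-stage outputs so a rerun can
be checked byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr, degattr, epigenome, normx, simdata, stochastic

__all__ = ["RunConfig", "run_pipeline", "classify_dataset"]


@dataclass
class RunConfig:
    """All pipeline thresholds, at their published defaults."""

    outdir: str = "aireclass_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "classify",
        "stochasticity",
        "coexpr",
        "spike",
    )
    # attribution / DEG
    attribution_sig_p: float = 1e-5
    z_gap: float = 1.0
    deg_p_max: float = 0.05
    min_frac: float = 0.05
    # stochasticity
    quantile: float = 0.975
    threshold_frac: float = 0.25
    # co-expression
    corr_threshold: float = 0.6
    min_reads: int = 5
    min_cells: int = 5
    # matching
    min_r: float = 0.2
    top_k: int = 2000
    # bulk / TRA
    bulk_fc_max: float = 0.5
    bulk_fdr_max: float = 0.05
    max_organs: int = 3
    # simulation
    sim: simdata.SimParams = field(default_factory=simdata.SimParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simdata.SimParams(**raw.pop("sim", {}))
        cfg = cls(**raw, sim=sim)
        return cfg

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def classify_dataset(adata, cfg: RunConfig | None = None) -> dict:
    """Run DEG + attribution + class labels on a simulated dataset.

    Returns a dict with the lognorm layer, the DEG table (WT Aire cluster vs
    KO counterpart), the Aire-DEG set, the attribution table over the WT
    mature clusters, the class labels and the maturation dynamics labels.
    """
    if cfg is None:
        cfg = RunConfig()
    counts = np.asarray(adata.X)
    layer = normx.lognormalize(counts)
    obs = adata.obs
    genes = adata.var["gene_id"].to_numpy()

    cluster = obs["cluster"].to_numpy()
    genotype = obs["genotype"].to_numpy()
    cells_a = np.flatnonzero((cluster == simdata.AIRE_CLUSTER) & (genotype == "WT"))
    cells_b = np.flatnonzero(cluster == simdata.AIRE_KO_CLUSTER)
    deg = degattr.two_group_deg(layer, cells_a, cells_b, cfg.min_frac, gene_names=genes)
    aire_degs = degattr.extract_aire_degs(deg, p_max=cfg.deg_p_max)

    wt = genotype == "WT"
    mature = [simdata.AIRE_CLUSTER, *simdata.MIMETIC_CLUSTERS]
    keep = wt & np.isin(cluster, mature)
    attribution = degattr.attribute_genes(
        layer[keep],
        cluster[keep],
        cluster_ids=mature,
        gene_names=genes,
        sig_p=cfg.attribution_sig_p,
        z_gap=cfg.z_gap,
    )
    classes = degattr.classify_aire_degs(aire_degs, attribution, simdata.AIRE_CLUSTER)
    dynamics = degattr.classify_dynamics(
        layer[wt], cluster[wt], path=simdata.MATURATION_PATH, gene_names=genes
    )
    return {
        "layer": layer,
        "deg": deg,
        "aire_degs": aire_degs,
        "attribution": attribution,
        "classes": classes,
        "dynamics": dynamics,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "param_hash": cfg.param_hash(),
        "seed": cfg.seed,
        "outputs": {},
    }

    sim = simdata.SimParams(**{**asdict(cfg.sim), "seed": cfg.seed})
    adata = simdata.simulate_dataset(sim)
    if "simulate" in cfg.stages:
        simdata.write_dataset(adata, outdir / "simulated")
        manifest["outputs"]["simulate"] = "simulated/"

    result = None
    if {"classify", "stochasticity", "coexpr"} & set(cfg.stages):
        result = classify_dataset(adata, cfg)

    if "classify" in cfg.stages:
        tab = result["deg"].copy()
        tab["assigned_clusters"] = [
            ",".join(sorted(s)) for s in result["attribution"]["assigned_clusters"]
        ]
        tab["branch"] = result["attribution"]["branch"]
        tab["class"] = result["classes"]
        tab["dynamics"] = result["dynamics"]
        tab.to_csv(outdir / "classification.tsv", sep="\t")
        manifest["outputs"]["classify"] = "classification.tsv"

    if "stochasticity" in cfg.stages:
        obs = adata.obs
        wt_aire = (obs["cluster"] == simdata.AIRE_CLUSTER) & (obs["genotype"] == "WT")
        frac = stochastic.fraction_table(
            result["layer"][wt_aire.to_numpy()],
            obs.loc[wt_aire, "cluster"].to_numpy(),
            genes=adata.var["gene_id"].to_numpy(),
            q=cfg.quantile,
            frac=cfg.threshold_frac,
        )
        frac.to_csv(outdir / "expressing_fractions.tsv", sep="\t")
        manifest["outputs"]["stochasticity"] = "expressing_fractions.tsv"

    if "coexpr" in cfg.stages:
        stats = coexpr_stage(adata, result, cfg)
        pd.DataFrame([{k: v for k, v in stats.items() if not hasattr(v, "p")}]).to_csv(
            outdir / "connection_stats.tsv", sep="\t", index=False
        )
        manifest["outputs"]["coexpr"] = "connection_stats.tsv"

    if "spike" in cfg.stages:
        lib = simdata.simulate_spike_library(seed=cfg.seed + 101)
        fr = [
            epigenome.compute_frspike(t, s)
            for t, s in zip(lib["reads_target"], lib["reads_spike"])
        ]
        table = pd.DataFrame(
            {
                "sample": lib["sample"],
                "rqc_total": lib["depth"],
                "frspike": fr,
                "eff": lib["reads_in_peaks"] / lib["depth"],
            }
        )
        table = epigenome.scaling_factors(table)
        table.to_csv(outdir / "scaling_table.tsv", sep="\t", index=False)
        manifest["outputs"]["spike"] = "scaling_table.tsv"

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def coexpr_stage(adata, result, cfg: RunConfig) -> dict:
    """Connection statistics of driven vs enhanced classes on the dataset.

    Correlations for the driven class are computed over the Aire cluster and
    its KO counterpart; for the enhanced class over the mimetic clusters —
    mirroring the cell populations in which each class is active.
    """
    counts = np.asarray(adata.X)
    layer = result["layer"]
    obs = adata.obs
    genes = pd.Index(adata.var["gene_id"])
    classes = result["classes"]
    gene_meta = adata.var.set_index("gene_id")

    cluster = obs["cluster"].to_numpy()
    cells_driven = np.isin(cluster, [simdata.AIRE_CLUSTER, simdata.AIRE_KO_CLUSTER])
    cells_enh = np.isin(cluster, list(simdata.MIMETIC_CLUSTERS))

    conns = {}
    for name, cells in (("driven", cells_driven), ("enhanced", cells_enh)):
        members = classes.index[classes == f"aire_{name}"]
        cols = genes.get_indexer(members)
        keep = coexpr.filter_correlation_genes(
            counts[:, cols], cells=cells, min_reads=cfg.min_reads, min_cells=cfg.min_cells
        )
        cols = cols[keep]
        corr = coexpr.correlation_matrix(
            layer[:, cols], genes=genes[cols].to_numpy(), cells=cells
        )
        conns[name] = coexpr.extract_connections(corr, gene_meta, cfg.corr_threshold)
    return coexpr.connection_stats(conns["driven"], conns["enhanced"])
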