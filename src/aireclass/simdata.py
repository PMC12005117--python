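"""Synthetic single-cell datasets with the statistical structure of the
Aire target-gene analysis, with recorded ground truth.

The generator emulates a thymic medullary epithelial (mTEC) single-cell
experiment:

* a cluster design in which the Aire-expressing mature cluster exists only
  in wild-type (WT) animals, with a knockout (KO) counterpart cluster;
* *Aire-driven* genes that fire stochastically — an independent Bernoulli
  gate per cell — in a minority (default 13.1%) of Aire-cluster WT cells,
  and are silent everywhere else;
* *Aire-enhanced* genes organised into latent co-expression modules that are
  active in designated mimetic-cell clusters in every genotype, plus the
  same stochastic gate in the WT Aire cluster;
* *Aire-neutral* genes drawn from one distribution everywhere;
* cluster marker genes so that clusters are separable for label transfer;
* genomic gene positions in which a fraction of Aire-driven genes form
  close intra-chromosomal pairs (median separation 20.4 kb) sharing one
  expression gate — the source of intra-chromosomal co-expression;
* dual-genome spike-in sequencing libraries and piecewise-constant signal
  tracks with peak sets, for the epigenomic normalization stages.

Counts follow a negative binomial with log-normal per-cell size factors.
Ground truth (class, module, home cluster, pair identity, spike-in
parameters) is emitted alongside the data; no analysis stage reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "build_genome",
    "build_design",
    "simulate_counts",
    "simulate_dataset",
    "simulate_spike_library",
    "simulate_tracks_peaks",
    "write_dataset",
    "write_bed",
    "write_bedgraph",
]

#: default chromosome sizes (10 autosomes, 100 Mb each)
DEFAULT_CHROM_SIZES = {f"chr{i}": 100_000_000 for i in range(1, 11)}

AIRE_CLUSTER = "aire"
AIRE_KO_CLUSTER = "aire_ko"
MIMETIC_CLUSTERS = ("mim1", "mim2", "mim3")
MATURATION_PATH = ("low", "mid", AIRE_CLUSTER)

#: cells per (cluster, genotype) in the default design
DEFAULT_DESIGN = {
    ("low", "WT"): 150,
    ("low", "Aire-KO"): 150,
    ("mid", "WT"): 150,
    ("mid", "Aire-KO"): 150,
    (AIRE_CLUSTER, "WT"): 500,
    (AIRE_KO_CLUSTER, "Aire-KO"): 300,
    ("mim1", "WT"): 100,
    ("mim1", "Aire-KO"): 100,
    ("mim2", "WT"): 100,
    ("mim2", "Aire-KO"): 100,
    ("mim3", "WT"): 100,
    ("mim3", "Aire-KO"): 100,
}


@dataclass
class SimParams:
    """Generation parameters. Defaults are the study conditions the analysis
    is meant to recover.

    p_express is the per-cell probability that an Aire-dependent gene fires
    in an Aire-cluster WT cell (13.1%); pair_median_bp is the target median
    TSS separation of designated adjacent Aire-driven pairs (20.4 kb).
    """

    n_driven: int = 500
    n_enhanced: int = 500
    n_neutral: int = 500
    n_markers_per_cluster: int = 40
    p_express: float = 0.131
    n_modules: int = 20
    adjacency_fraction: float = 0.2
    pair_median_bp: float = 20_400.0
    pair_sigma: float = 0.6
    high_mean: float = 30.0
    marker_mean: float = 20.0
    neutral_mean_log: float = 0.7  # ln-scale location of neutral gene means
    neutral_mean_sigma: float = 0.8
    base_off_mean: float = 0.01
    nb_shape: float = 10.0
    module_activity_shape: float = 1.5
    size_factor_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_express <= 1.0:
            raise ValueError("p_express must lie in [0, 1]")
        if not 0.0 <= self.adjacency_fraction <= 1.0:
            raise ValueError("adjacency_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def build_genome(
    n_genes: int,
    chrom_sizes: dict[str, int] | None = None,
    adjacency_fraction: float = 0.0,
    seed: int = 0,
    pair_median_bp: float = 20_400.0,
    pair_sigma: float = 0.6,
    pair_members=None,
) -> pd.DataFrame:
    """Place ``n_genes`` on a genome, designating close intra-chromosomal pairs.

    Genes are placed uniformly on chromosomes proportional to size, except
    designated pairs: the second member of a pair is placed downstream of the
    first at a log-normal TSS separation whose median is ``pair_median_bp``.
    ``pair_members`` may list explicit gene indices (taken two at a time);
    otherwise the first ``2 * floor(adjacency_fraction * n_genes / 2)`` genes
    are paired.  Returns a frame with gene_id, chrom, tss, strand, length_bp
    and pair_id (NA for unpaired genes).
    """
    if chrom_sizes is None:
        chrom_sizes = DEFAULT_CHROM_SIZES
    if not chrom_sizes:
        raise ValueError("chrom_sizes must be nonempty")
    if not 0.0 <= adjacency_fraction <= 1.0:
        raise ValueError("adjacency_fraction must lie in [0, 1]")
    min_size = min(chrom_sizes.values())
    if min_size < 1_000_000 and n_genes > 0:
        raise ValueError("chromosome too small to host requested genes")

    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    chrom_idx = rng.choice(len(chroms), size=n_genes, p=probs)
    tss = np.array(
        [rng.integers(0, chrom_sizes[chroms[i]] - 100_000) for i in chrom_idx],
        dtype=np.int64,
    )
    strand = rng.choice(["+", "-"], size=n_genes)
    length = np.maximum(200, rng.lognormal(np.log(1500.0), 0.5, size=n_genes)).astype(np.int64)

    pair_id = np.full(n_genes, -1, dtype=np.int64)
    if pair_members is None:
        n_pairs = int(np.floor(adjacency_fraction * n_genes / 2))
        pair_members = np.arange(2 * n_pairs)
    pair_members = np.asarray(pair_members, dtype=int)
    mu = np.log(pair_median_bp)
    for k in range(len(pair_members) // 2):
        i, j = pair_members[2 * k], pair_members[2 * k + 1]
        gap = int(round(rng.lognormal(mu, pair_sigma)))
        chrom_i = chrom_idx[i]
        limit = chrom_sizes[chroms[chrom_i]] - 100_000
        if tss[i] + gap >= limit:  # reflect back inside the chromosome
            tss[i] = max(0, limit - gap - 1)
        chrom_idx[j] = chrom_i
        tss[j] = tss[i] + gap
        pair_id[i] = pair_id[j] = k

    meta = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": [chroms[i] for i in chrom_idx],
            "tss": tss,
            "strand": strand,
            "length_bp": length,
            "pair_id": pair_id,
        }
    ).set_index("gene_id", drop=False)
    meta.index.name = None
    return meta


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(
    cluster_sizes: dict[tuple[str, str], int] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Build the per-cell annotation table for a cluster x genotype design.

    ``cluster_sizes`` maps (cluster, genotype) to a cell count.  The design
    must declare the WT-only Aire cluster and its KO counterpart.
    """
    if cluster_sizes is None:
        cluster_sizes = DEFAULT_DESIGN
    clusters = {c for c, _ in cluster_sizes}
    if AIRE_CLUSTER not in clusters or AIRE_KO_CLUSTER not in clusters:
        raise ValueError("design must declare the Aire cluster and its KO counterpart")
    if any(n < 0 for n in cluster_sizes.values()):
        raise ValueError("negative cluster size")
    if any(g != "WT" and c == AIRE_CLUSTER and n > 0 for (c, g), n in cluster_sizes.items()):
        raise ValueError("the Aire cluster is WT-only")

    rows = []
    for (cluster, genotype), n in sorted(cluster_sizes.items()):
        for _ in range(n):
            rows.append((cluster, genotype))
    meta = pd.DataFrame(rows, columns=["cluster", "genotype"])
    meta["cell_id"] = [f"c{i:05d}" for i in range(len(meta))]
    meta["sample"] = meta["genotype"].str.replace("-", "").str.lower() + "_1"
    meta["age_group"] = "adult"
    meta = meta.set_index("cell_id", drop=False)[
        ["cell_id", "cluster", "genotype", "sample", "age_group"]
    ]
    meta.index.name = None
    return meta


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mu: np.ndarray, shape: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with mean ``mu``."""
    lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) / shape), 0.0)
    return rng.poisson(lam)


def simulate_counts(
    gene_meta: pd.DataFrame, cell_meta: pd.DataFrame, params: SimParams
) -> ad.AnnData:
    """Draw the count matrix given annotated genes, cells and parameters.

    Requires ``truth_class`` in ``gene_meta`` (plus ``module_id``,
    ``home_cluster`` and ``pair_id`` where applicable).  Returns an AnnData
    (cells x genes, integer X) carrying both annotation frames and the
    latent module activities in ``obsm['module_activity']``.
    """
    if "truth_class" not in gene_meta.columns or gene_meta["truth_class"].isna().any():
        raise ValueError("truth classes must be assigned for every gene")

    rng = np.random.default_rng(params.seed + 1)
    n_cells = len(cell_meta)
    n_genes = len(gene_meta)
    cls = gene_meta["truth_class"].to_numpy()
    cluster = cell_meta["cluster"].to_numpy()
    genotype = cell_meta["genotype"].to_numpy()

    mu = np.full((n_cells, n_genes), params.base_off_mean, dtype=float)

    # Aire-neutral genes: one gene-specific mean everywhere
    neutral = cls == "aire_neutral"
    neutral_means = rng.lognormal(
        params.neutral_mean_log, params.neutral_mean_sigma, size=int(neutral.sum())
    )
    mu[:, neutral] = neutral_means[None, :]

    # stochastic Bernoulli gates in the WT Aire cluster, shared within pairs
    aire_wt = (cluster == AIRE_CLUSTER) & (genotype == "WT")
    gated = (cls == "aire_driven") | (cls == "aire_enhanced")
    gated_idx = np.flatnonzero(gated)
    pair_id = gene_meta["pair_id"].to_numpy() if "pair_id" in gene_meta else np.full(n_genes, -1)
    gate = np.zeros((int(aire_wt.sum()), n_genes), dtype=bool)
    done = np.zeros(n_genes, dtype=bool)
    for g in gated_idx:
        if done[g]:
            continue
        members = [g]
        if pair_id[g] >= 0:
            members = list(np.flatnonzero(pair_id == pair_id[g]))
        draw = rng.random(gate.shape[0]) < params.p_express
        for m in members:
            gate[:, m] = draw
            done[m] = True
    sub = mu[aire_wt]
    sub[gate] = params.high_mean
    mu[aire_wt] = sub

    # Aire-enhanced modules: per-cell Gamma activity shared by module genes,
    # active in the module's home mimetic cluster in every genotype
    activity = rng.gamma(
        params.module_activity_shape,
        1.0 / params.module_activity_shape,
        size=(n_cells, params.n_modules),
    )
    enhanced = np.flatnonzero(cls == "aire_enhanced")
    module_id = gene_meta["module_id"].to_numpy()
    home = gene_meta["home_cluster"].to_numpy(dtype=object)
    for g in enhanced:
        m = int(module_id[g])
        in_home = cluster == home[g]
        mu[in_home, g] = params.high_mean * activity[in_home, m]

    # cluster markers: constant high mean in the home cluster, any genotype
    markers = np.flatnonzero(cls == "mimetic_marker")
    for g in markers:
        mu[cluster == home[g], g] = params.marker_mean

    size_factors = rng.lognormal(0.0, params.size_factor_sigma, size=n_cells)
    counts = _nb_sample(rng, mu * size_factors[:, None], params.nb_shape)

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=cell_meta.copy(),
        var=gene_meta.copy(),
    )
    adata.obsm["module_activity"] = activity
    adata.uns["sim_params"] = asdict(params)
    return adata


def simulate_dataset(params: SimParams | None = None) -> ad.AnnData:
    """Generate a complete annotated dataset under the default study design.

    Builds the genome (with adjacent Aire-driven pairs), the cluster x
    genotype cell design, assigns truth classes and modules, and draws
    counts.  One master seed drives child streams per stage; the seeds are
    recorded in ``uns``.
    """
    if params is None:
        params = SimParams()
    marker_clusters = ("low", "mid") + tuple(MIMETIC_CLUSTERS)
    n_markers = params.n_markers_per_cluster * len(marker_clusters)
    n_genes = params.n_driven + params.n_enhanced + params.n_neutral + n_markers

    # class layout: driven block first so paired members are driven genes
    truth = np.array(
        ["aire_driven"] * params.n_driven
        + ["aire_enhanced"] * params.n_enhanced
        + ["aire_neutral"] * params.n_neutral
        + ["mimetic_marker"] * n_markers,
        dtype=object,
    )
    n_pairs = int(np.floor(params.adjacency_fraction * params.n_driven / 2))
    pair_members = np.arange(2 * n_pairs)

    genome = build_genome(
        n_genes,
        adjacency_fraction=0.0,
        seed=params.seed + 11,
        pair_median_bp=params.pair_median_bp,
        pair_sigma=params.pair_sigma,
        pair_members=pair_members,
    )
    genome["truth_class"] = truth

    module_id = np.full(n_genes, -1, dtype=np.int64)
    home = np.full(n_genes, None, dtype=object)
    enhanced_idx = np.flatnonzero(truth == "aire_enhanced")
    module_id[enhanced_idx] = np.arange(len(enhanced_idx)) % params.n_modules
    for m in range(params.n_modules):
        home_cluster = MIMETIC_CLUSTERS[m % len(MIMETIC_CLUSTERS)]
        home[enhanced_idx[module_id[enhanced_idx] == m]] = home_cluster
    marker_idx = np.flatnonzero(truth == "mimetic_marker")
    for k, g in enumerate(marker_idx):
        home[g] = marker_clusters[k // params.n_markers_per_cluster]
    genome["module_id"] = module_id
    genome["home_cluster"] = home

    cells = build_design(seed=params.seed + 13)
    adata = simulate_counts(genome, cells, params)
    adata.uns["seeds"] = {
        "master": params.seed,
        "genome": params.seed + 11,
        "design": params.seed + 13,
        "counts": params.seed + 1,
    }
    return adata


# ---------------------------------------------------------------------------
# spike-in libraries
# ---------------------------------------------------------------------------

def simulate_spike_library(
    n_samples: int = 20,
    depth_range: tuple[float, float] = (5e5, 2e6),
    frspike_range: tuple[float, float] = (0.2, 0.6),
    eff_range: tuple[float, float] = (0.25, 0.45),
    seed: int = 0,
    genome_size_target: float = 2.49e9,
    genome_size_spike: float = 2.86e9,
) -> pd.DataFrame:
    """Simulate dual-genome spike-in libraries with recorded truth.

    Per sample: a true spike-in cell fraction (FrSpike) and assay efficiency
    (Eff) are drawn uniformly from the given ranges; reads are split
    binomially between spike and target genomes so that the genome-size-
    normalized estimator recovers FrSpike, and reads-in-peaks are binomial
    with rate Eff.
    """
    for lo, hi in (frspike_range, eff_range):
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("fraction ranges must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    depth = rng.integers(int(depth_range[0]), int(depth_range[1]) + 1, size=n_samples)
    f = rng.uniform(*frspike_range, size=n_samples)
    eff = rng.uniform(*eff_range, size=n_samples)
    # read-level spike fraction implied by the cell fraction f
    q = f * genome_size_spike / (f * genome_size_spike + (1 - f) * genome_size_target)
    reads_spike = rng.binomial(depth, q)
    reads_target = depth - reads_spike
    rip = rng.binomial(depth, eff)
    return pd.DataFrame(
        {
            "sample": [f"s{i:02d}" for i in range(n_samples)],
            "depth": depth,
            "reads_target": reads_target,
            "reads_spike": reads_spike,
            "reads_in_peaks": rip,
            "true_frspike": f,
            "true_eff": eff,
        }
    )


# ---------------------------------------------------------------------------
# tracks and peaks
# ---------------------------------------------------------------------------

def simulate_tracks_peaks(
    gene_meta: pd.DataFrame,
    peak_offsets: dict[str, int] | None = None,
    n_background_peaks: int = 50,
    segment_bp: int = 10_000,
    track_mean: float = 1.0,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a peak set at controlled TSS offsets plus a piecewise track.

    ``peak_offsets`` maps gene_id -> signed offset of the peak midpoint from
    its TSS (default: a peak at the TSS of every 10th gene).  The signal
    track tiles each chromosome's gene-bearing span with ``segment_bp``
    segments of Gamma-distributed value (mean ``track_mean``), so the mean
    over any interval is exactly computable.
    """
    if chrom_sizes is None:
        chrom_sizes = DEFAULT_CHROM_SIZES
    rng = np.random.default_rng(seed)
    if peak_offsets is None:
        peak_offsets = {g: 0 for g in gene_meta["gene_id"].iloc[::10]}

    rows = []
    width = 400
    for gene_id, off in peak_offsets.items():
        g = gene_meta.loc[gene_id]
        mid = int(g["tss"]) + int(off)
        rows.append((g["chrom"], max(0, mid - width // 2), mid + width // 2, f"peak_{gene_id}", 0.001))
    for k in range(n_background_peaks):
        chrom = rng.choice(list(chrom_sizes))
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        rows.append((chrom, start, start + width, f"bg_{k}", 0.001))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "q_value"])
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    track_rows = []
    for chrom in sorted(set(gene_meta["chrom"])):
        span = int(gene_meta.loc[gene_meta["chrom"] == chrom, "tss"].max()) + 50_000
        edges = np.arange(0, span + segment_bp, segment_bp)
        values = rng.gamma(2.0, track_mean / 2.0, size=len(edges) - 1)
        for s, e, v in zip(edges[:-1], edges[1:], values):
            track_rows.append((chrom, int(s), int(e), float(v)))
    track = pd.DataFrame(track_rows, columns=["chrom", "start", "end", "value"])
    return peaks, track


# ---------------------------------------------------------------------------
# writers (plain-text exchange formats)
# ---------------------------------------------------------------------------

def write_dataset(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as MatrixMarket (genes x cells) plus sidecar TSVs.

    Emits matrix.mtx, features.tsv, barcodes.tsv, gene_meta.tsv (BED-like,
    0-based), cell_meta.tsv, truth.tsv and run_meta.json.
    """
    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(adata.X.T))
    adata.var["gene_id"].to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    adata.obs["cell_id"].to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    gm = adata.var.copy()
    gm["start"] = gm["tss"]
    gm["end"] = gm["tss"] + gm["length_bp"]
    gm[["chrom", "start", "end", "gene_id", "strand", "length_bp"]].to_csv(
        outdir / "gene_meta.tsv", sep="\t", index=False
    )
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    truth_cols = [c for c in ("gene_id", "truth_class", "module_id", "home_cluster", "pair_id") if c in adata.var]
    adata.var[truth_cols].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = {k: adata.uns[k] for k in ("sim_params", "seeds") if k in adata.uns}
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a peak set as BED6 (score column reused for the q value)."""
    out = peaks.copy()
    out["score"] = out.get("q_value", 0.0)
    out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    """Write a signal track as bedGraph with fixed-precision values."""
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.{precision}f}\n")
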