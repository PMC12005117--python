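import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aireclass as ac
from aireclass import simdata
from aireclass.simdata import (
    SimParams,
    build_design,
    build_genome,
    simulate_spike_library,
    simulate_tracks_peaks,
)


class TestBuildGenome:
    def test_no_pairs_case(self):
        meta = build_genome(100, {"chr1": 5_000_000, "chr2": 5_000_000}, 0.0, seed=0)
        assert len(meta) == 100
        assert (meta["pair_id"] == -1).all()
        assert set(meta["chrom"]) <= {"chr1", "chr2"}

    def test_pair_distance_median_near_target(self):
        meta = build_genome(200, adjacency_fraction=0.1, seed=3)  # 10 pairs
        paired = meta[meta["pair_id"] >= 0]
        assert len(paired) == 20
        dists = paired.groupby("pair_id")["tss"].agg(lambda t: t.max() - t.min())
        chroms = paired.groupby("pair_id")["chrom"].nunique()
        assert (chroms == 1).all()
        assert 10_000 <= dists.median() <= 40_000

    def test_determinism(self):
        a = build_genome(50, adjacency_fraction=0.2, seed=9)
        b = build_genome(50, adjacency_fraction=0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_genome(10, {"chr1": 1000}, 0.0, seed=0)

    def test_invariants(self):
        meta = build_genome(300, seed=1)
        assert meta["gene_id"].is_unique
        assert (meta["tss"] >= 0).all()
        assert (meta["length_bp"] > 0).all()


class TestBuildDesign:
    def test_wt_only_aire_cluster(self):
        meta = build_design(seed=0)
        aire = meta[meta["cluster"] == simdata.AIRE_CLUSTER]
        assert len(aire) == 500
        assert (aire["genotype"] == "WT").all()

    def test_total_conservation(self):
        meta = build_design(seed=0)
        assert len(meta) == sum(simdata.DEFAULT_DESIGN.values())

    def test_determinism(self):
        pd.testing.assert_frame_equal(build_design(seed=4), build_design(seed=4))

    def test_negative_size_rejected(self):
        design = dict(simdata.DEFAULT_DESIGN)
        design[("low", "WT")] = -1
        with pytest.raises(ValueError):
            build_design(design)

    def test_ko_cells_in_aire_cluster_rejected(self):
        design = dict(simdata.DEFAULT_DESIGN)
        design[(simdata.AIRE_CLUSTER, "Aire-KO")] = 5
        with pytest.raises(ValueError):
            build_design(design)


class TestSimulateCounts:
    def test_missing_truth_classes_rejected(self):
        genome = build_genome(10, seed=0)
        cells = build_design(seed=0)
        with pytest.raises(ValueError):
            simdata.simulate_counts(genome, cells, SimParams())

    def test_driven_expressing_fraction_matches_gate(self, default_dataset):
        """Nonzero-count fraction of driven genes in Aire-cluster WT cells
        sits within 3 binomial SE of the gate probability."""
        adata = default_dataset
        p = adata.uns["sim_params"]["p_express"]
        obs = adata.obs
        mask = ((obs["cluster"] == simdata.AIRE_CLUSTER) & (obs["genotype"] == "WT")).to_numpy()
        n = int(mask.sum())
        driven = (adata.var["truth_class"] == "aire_driven").to_numpy()
        frac = (np.asarray(adata.X)[mask][:, driven] > 0).mean(axis=0)
        se = np.sqrt(p * (1 - p) / n)
        # baseline stray counts push the nonzero fraction slightly above the gate
        assert abs(np.median(frac) - p) < 3 * se

    def test_neutral_null_p_uniform(self):
        """Rank-test p of neutral genes, WT Aire cluster vs KO counterpart,
        is uniform across genes (the contrast carries no signal for them)."""
        adata = ac.simulate_dataset(SimParams(seed=7, n_driven=50, n_enhanced=50, n_neutral=200))
        obs = adata.obs
        a = ((obs["cluster"] == simdata.AIRE_CLUSTER) & (obs["genotype"] == "WT")).to_numpy()
        b = (obs["cluster"] == simdata.AIRE_KO_CLUSTER).to_numpy()
        neutral = (adata.var["truth_class"] == "aire_neutral").to_numpy()
        x = np.asarray(adata.X, dtype=float)
        res = stats.mannwhitneyu(x[a][:, neutral], x[b][:, neutral], axis=0, method="asymptotic")
        ks = stats.kstest(res.pvalue, "uniform")
        assert ks.pvalue > 0.01

    def test_module_correlation_structure(self, default_dataset):
        """Within-module gene pairs correlate strongly in mimetic cells;
        different modules sharing a home cluster do not."""
        adata = default_dataset
        from aireclass.normx import lognormalize

        layer = lognormalize(np.asarray(adata.X))
        var = adata.var.reset_index(drop=True)
        mask = np.isin(adata.obs["cluster"].to_numpy(), simdata.MIMETIC_CLUSTERS)
        enh = var[var["truth_class"] == "aire_enhanced"]
        within, across = [], []
        for m in range(6):
            idx = enh.index[enh["module_id"] == m].to_numpy()
            r = np.corrcoef(layer[mask][:, idx], rowvar=False)
            within.append(r[np.triu_indices(len(idx), 1)].mean())
            # module m + 3 shares the home cluster (round-robin placement)
            other = enh.index[enh["module_id"] == m + 3].to_numpy()
            home = enh.loc[idx[0], "home_cluster"]
            cells = (adata.obs["cluster"] == home).to_numpy()
            rc = np.corrcoef(layer[cells][:, np.r_[idx[:5], other[:5]]], rowvar=False)
            across.append(rc[:5, 5:].mean())
        assert np.mean(within) > 0.6
        assert abs(np.mean(across)) < 0.2

    def test_neutral_genotype_exchangeability(self):
        """Neutral gene counts are exchangeable across genotypes within a
        cluster: rank-test p > 0.01 in at least 95% of replicates."""
        adata = ac.simulate_dataset(SimParams(seed=5, n_driven=20, n_enhanced=20, n_neutral=100))
        obs = adata.obs
        wt = ((obs["cluster"] == "low") & (obs["genotype"] == "WT")).to_numpy()
        ko = ((obs["cluster"] == "low") & (obs["genotype"] == "Aire-KO")).to_numpy()
        neutral = (adata.var["truth_class"] == "aire_neutral").to_numpy()
        x = np.asarray(adata.X, dtype=float)
        res = stats.mannwhitneyu(x[wt][:, neutral], x[ko][:, neutral], axis=0, method="asymptotic")
        assert (res.pvalue > 0.01).mean() >= 0.95

    def test_dataset_determinism(self):
        a = ac.simulate_dataset(SimParams(seed=2, n_driven=30, n_enhanced=30, n_neutral=30))
        b = ac.simulate_dataset(SimParams(seed=2, n_driven=30, n_enhanced=30, n_neutral=30))
        np.testing.assert_array_equal(np.asarray(a.X), np.asarray(b.X))
        pd.testing.assert_frame_equal(a.var, b.var)


class TestSpikeLibrary:
    def test_determinism(self):
        a = simulate_spike_library(seed=6)
        b = simulate_spike_library(seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_recovery_within_binomial_error(self):
        from aireclass.epigenome import compute_frspike

        lib = simulate_spike_library(n_samples=20, seed=8)
        for row in lib.itertuples():
            fr = compute_frspike(row.reads_target, row.reads_spike)
            se = np.sqrt(row.true_frspike * (1 - row.true_frspike) / row.depth)
            assert abs(fr - row.true_frspike) < 3 * se + 1e-12
            eff = row.reads_in_peaks / row.depth
            se_eff = np.sqrt(row.true_eff * (1 - row.true_eff) / row.depth)
            assert abs(eff - row.true_eff) < 3 * se_eff + 1e-12

    def test_range_validation(self):
        with pytest.raises(ValueError):
            simulate_spike_library(frspike_range=(0.0, 1.2))


class TestTracksPeaks:
    def test_peak_at_tss_gives_zero_distance(self):
        meta = build_genome(20, seed=0)
        gene = meta["gene_id"].iloc[0]
        peaks, _ = simulate_tracks_peaks(meta, peak_offsets={gene: 0}, n_background_peaks=0)
        from aireclass.epigenome import peak_proximity

        tss = meta.loc[[gene], ["chrom", "tss"]]
        prox = peak_proximity(peaks, tss)
        assert prox.loc[gene, "nearest_distance"] == 0.0

    def test_track_segments_partition(self):
        meta = build_genome(20, seed=0)
        _, track = simulate_tracks_peaks(meta, n_background_peaks=0)
        for _, g in track.groupby("chrom"):
            assert (g["start"].to_numpy()[1:] == g["end"].to_numpy()[:-1]).all()

    def test_written_output_deterministic(self, tmp_path):
        meta = build_genome(20, seed=0)
        for rep in ("a", "b"):
            peaks, track = simulate_tracks_peaks(meta, seed=5)
            simdata.write_bed(peaks, tmp_path / f"peaks_{rep}.bed")
            simdata.write_bedgraph(track, tmp_path / f"track_{rep}.bedgraph")
        assert (tmp_path / "peaks_a.bed").read_bytes() == (tmp_path / "peaks_b.bed").read_bytes()
        assert (
            tmp_path / "track_a.bedgraph"
        ).read_bytes() == (tmp_path / "track_b.bedgraph").read_bytes()


class TestWriters:
    def test_roundtrip_matrix_and_truth(self, tmp_path):
        adata = ac.simulate_dataset(SimParams(seed=3, n_driven=10, n_enhanced=10, n_neutral=10))
        simdata.write_dataset(adata, tmp_path)
        from scipy import io as spio

        m = spio.mmread(tmp_path / "matrix.mtx")
        assert m.shape == (adata.shape[1], adata.shape[0])  # genes x cells on disk
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert set(truth["truth_class"]) <= {
            "aire_driven",
            "aire_enhanced",
            "aire_neutral",
            "mimetic_marker",
        }
        assert (tmp_path / "run_meta.json").exists()
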