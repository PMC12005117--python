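import numpy as np
import pandas as pd
import pytest

from aireclass.epigenome import (
    compute_frspike,
    locus_density,
    peak_proximity,
    scale_track,
    scaling_factors,
    tss_profile,
)
from aireclass.simdata import simulate_spike_library


class TestFrSpike:
    def test_formula_with_published_genome_sizes(self):
        assert compute_frspike(9e6, 1e6) == pytest.approx(0.0882, abs=5e-4)

    def test_equal_counts_equal_genomes(self):
        assert compute_frspike(5e5, 5e5, 1e9, 1e9) == 0.5

    def test_no_spike_reads(self):
        assert compute_frspike(1e6, 0) == 0.0

    def test_scale_invariance(self):
        a = compute_frspike(3e6, 1e6)
        b = compute_frspike(3e7, 1e7)
        assert a == pytest.approx(b, rel=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_frspike(0, 0)


class TestScalingFactors:
    def _table(self, **over):
        base = {
            "rqc_total": [1e6, 2e6],
            "frspike": [0.5, 0.5],
            "eff": [0.5, 0.5],
        }
        base.update(over)
        return pd.DataFrame(base)

    def test_closed_form(self):
        out = scaling_factors(self._table())
        assert out.loc[0, "sfabs"] == pytest.approx(4e-6)

    def test_doubling_rqc_halves_sfabs(self):
        out = scaling_factors(self._table())
        assert out.loc[1, "sfabs"] == pytest.approx(out.loc[0, "sfabs"] / 2)

    def test_sfrel_max_is_one(self):
        out = scaling_factors(
            self._table(
                rqc_total=[1e6, 3e6, 2e6], frspike=[0.5, 0.5, 0.5], eff=[0.5, 0.5, 0.5]
            )
        )
        assert out["sfrel"].max() == 1.0
        assert out.loc[0, "sfrel"] == 1.0  # smallest library scales least

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            scaling_factors(self._table(frspike=[1.0, 0.5]))
        with pytest.raises(ValueError):
            scaling_factors(self._table(eff=[0.0, 0.5]))

    def test_recovery_from_simulated_library(self):
        """FrSpike and Eff recomputed from simulated reads land within 3
        binomial SE of the generating truth."""
        lib = simulate_spike_library(n_samples=20, seed=2)
        fr = np.array(
            [compute_frspike(t, s) for t, s in zip(lib["reads_target"], lib["reads_spike"])]
        )
        se = np.sqrt(lib["true_frspike"] * (1 - lib["true_frspike"]) / lib["depth"])
        assert (np.abs(fr - lib["true_frspike"]) < 3 * se).all()
        eff = lib["reads_in_peaks"] / lib["depth"]
        se_eff = np.sqrt(lib["true_eff"] * (1 - lib["true_eff"]) / lib["depth"])
        assert (np.abs(eff - lib["true_eff"]) < 3 * se_eff).all()


class TestScaleTrack:
    def _track(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 100, 200],
                "end": [100, 200, 350],
                "value": [10.0, 4.0, 2.0],
            }
        )

    def test_values_scaled(self):
        out = scale_track(self._track(), 0.5)
        assert list(out["value"]) == [5.0, 2.0, 1.0]

    def test_identity_at_one(self):
        pd.testing.assert_frame_equal(scale_track(self._track(), 1.0), self._track())

    def test_area_scales_exactly(self):
        t = self._track()
        area = ((t["end"] - t["start"]) * t["value"]).sum()
        s = scale_track(t, 0.3)
        scaled_area = ((s["end"] - s["start"]) * s["value"]).sum()
        assert scaled_area == pytest.approx(0.3 * area)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_track(self._track(), 0.0)


class TestLocusDensity:
    def test_uniform_track(self):
        track = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1_000_000], "value": [3.0]}
        )
        loci = pd.DataFrame(
            {"chrom": ["chr1"], "start": [200_000], "end": [210_000]}, index=["g"]
        )
        assert locus_density(track, loci).loc["g"] == pytest.approx(3.0)

    def test_half_covered_window(self):
        # track covers exactly half the +/-10 kb window at 2v -> mean v
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_000 + 2]}, index=["g"])
        window = 2 + 20_000
        track = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [window // 2], "value": [2.0]}
        )
        assert locus_density(track, loci).loc["g"] == pytest.approx(1.0, rel=1e-3)

    def test_disjoint_track(self):
        track = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "value": [5.0]})
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}, index=["g"])
        assert locus_density(track, loci).loc["g"] == 0.0

    def test_empty_locus_rejected(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "value": [1.0]})
        loci = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [50]}, index=["g"])
        with pytest.raises(ValueError):
            locus_density(track, loci)

    def test_depth_difference_normalized_away(self):
        """Two samples with the same enrichment but 2x depth difference give
        locus densities within 5% after Sfrel scaling."""
        rng = np.random.default_rng(3)
        edges = np.arange(0, 500_000, 10_000)
        enrich = rng.gamma(2.0, 1.0, size=len(edges) - 1)
        tracks = {}
        meta = []
        for name, depth in (("a", 1e6), ("b", 2e6)):
            tracks[name] = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": edges[:-1],
                    "end": edges[1:],
                    "value": enrich * depth / 1e6,
                }
            )
            meta.append({"sample": name, "rqc_total": depth, "frspike": 0.4, "eff": 0.35})
        table = scaling_factors(pd.DataFrame(meta))
        loci = pd.DataFrame(
            {"chrom": "chr1", "start": [100_000, 300_000], "end": [110_000, 320_000]},
            index=["g1", "g2"],
        )
        dens = {
            row.sample: locus_density(
                scale_track(tracks[row.sample], row.sfrel), loci
            )
            for row in table.itertuples()
        }
        np.testing.assert_allclose(dens["a"], dens["b"], rtol=0.05)


class TestTssProfile:
    def test_insertion_at_tss_center_bin(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "pos": [5000]})
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [5000], "strand": ["+"]})
        profile = tss_profile(frags, tss, window=100)
        assert profile[100] == 1.0
        assert profile.sum() == 1.0

    def test_group_scaling_divisor(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "pos": [5000]})
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [5000], "strand": ["+"]})
        profile = tss_profile(frags, tss, window=100, n_cells=2, mean_depth=50.0)
        assert profile[100] == pytest.approx(1 / 100)

    def test_minus_strand_reversed(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "pos": [5100]})
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [5000], "strand": ["-"]})
        profile = tss_profile(frags, tss, window=200)
        assert profile[200 - 100] == 1.0  # +100 offset lands in the -100 bin

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_profile(pd.DataFrame({"chrom": [], "pos": []}), pd.DataFrame())


class TestPeakProximity:
    def _tss(self):
        return pd.DataFrame({"chrom": ["chr1"], "tss": [100_000]}, index=["g"])

    def test_midpoint_inside_window_counted(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [104_800], "end": [105_200]}  # midpoint +5 kb
        )
        out = peak_proximity(peaks, self._tss())
        assert out.loc["g", "peak_count"] == 1

    def test_midpoint_outside_window_not_counted(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [110_300], "end": [110_700]}  # midpoint +10.5 kb
        )
        out = peak_proximity(peaks, self._tss())
        assert out.loc["g", "peak_count"] == 0

    def test_nearest_edge_distance(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [96_600, 109_000],  # edges at -3 kb and +9 kb
                "end": [97_000, 109_400],
            }
        )
        out = peak_proximity(peaks, self._tss())
        assert out.loc["g", "nearest_distance"] == 3_000

    def test_tss_inside_peak_zero_distance(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [99_900], "end": [100_100]})
        out = peak_proximity(peaks, self._tss())
        assert out.loc["g", "nearest_distance"] == 0.0

    def test_empty_peak_set_sentinel(self):
        peaks = pd.DataFrame({"chrom": pd.Series([], dtype=str), "start": [], "end": []})
        out = peak_proximity(peaks, self._tss())
        assert np.isinf(out.loc["g", "nearest_distance"])
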