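"""CUT&Tag spike-in scaling and genomic signal statistics.

Spike-in normalization: the fraction of spike-in cells (FrSpike) is
estimated from reads mapped to each genome, normalized by effective genome
size; assay efficiency Eff = RiP/RQC; the absolute scaling factor is

    Sfabs = 1 / [RQC_total * (1 - FrSpike)] * 1 / Eff

and relative factors Sfrel = Sfabs / max(Sfabs) rescale signal tracks so
samples are comparable.  Downstream statistics: length-weighted mean signal
over gene loci +/- 10 kb, strand-aware TSS metaprofiles, and peak counts /
nearest-peak distances in a 20-kb TSS window.

Tracks are frames (chrom, start, end, value), 0-based half-open,
non-overlapping within a chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_frspike",
    "scaling_factors",
    "scale_track",
    "locus_density",
    "tss_profile",
    "peak_proximity",
]

GENOME_SIZE_TARGET = 2.49e9  # mm10 effective genome size
GENOME_SIZE_SPIKE = 2.86e9   # hg38 effective genome size


def compute_frspike(
    reads_target: float,
    reads_spike: float,
    genome_size_target: float = GENOME_SIZE_TARGET,
    genome_size_spike: float = GENOME_SIZE_SPIKE,
) -> float:
    """Spike-in cell fraction from per-genome read counts.

    FrSpike = (spike/G_spike) / (spike/G_spike + target/G_target).
    """
    if reads_target < 0 or reads_spike < 0:
        raise ValueError("read counts must be nonnegative")
    if reads_target == 0 and reads_spike == 0:
        raise ValueError("at least one genome must have reads")
    s = reads_spike / genome_size_spike
    t = reads_target / genome_size_target
    return float(s / (s + t))


def scaling_factors(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Sfabs and Sfrel from RQC totals, FrSpike and Eff.

    ``samples`` needs columns rqc_total, frspike, eff.  Returns a copy with
    sfabs and sfrel columns; max(sfrel) == 1 by construction.
    """
    for col in ("rqc_total", "frspike", "eff"):
        if col not in samples.columns:
            raise ValueError(f"missing column {col!r}")
    rqc = samples["rqc_total"].to_numpy(dtype=float)
    fr = samples["frspike"].to_numpy(dtype=float)
    eff = samples["eff"].to_numpy(dtype=float)
    if np.any(rqc <= 0):
        raise ValueError("RQC totals must be positive")
    if np.any(fr >= 1):
        raise ValueError("FrSpike must be below 1")
    if np.any(eff <= 0):
        raise ValueError("Eff must be positive")
    sfabs = 1.0 / (rqc * (1.0 - fr)) / eff
    out = samples.copy()
    out["sfabs"] = sfabs
    out["sfrel"] = sfabs / sfabs.max()
    return out


def scale_track(track: pd.DataFrame, sfrel: float) -> pd.DataFrame:
    """Multiply every track value by the relative scaling factor."""
    if sfrel <= 0:
        raise ValueError("Sfrel must be positive")
    out = track.copy()
    out["value"] = out["value"] * sfrel
    return out


def _interval_mean(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, lo: int, hi: int
) -> float:
    """Length-weighted mean of a sorted disjoint track over [lo, hi);
    uncovered bases contribute 0."""
    if hi <= lo:
        raise ValueError("empty locus")
    overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
    overlap = np.clip(overlap, 0, None)
    return float((overlap * values).sum() / (hi - lo))


def locus_density(
    track: pd.DataFrame, loci: pd.DataFrame, flank: int = 10_000
) -> pd.Series:
    """Mean signal over each locus extended by ``flank`` on both sides.

    ``loci`` needs chrom, start, end and an index of gene identifiers.
    Windows are clipped at 0; bases without track coverage count as 0.
    """
    by_chrom = {
        c: (
            g["start"].to_numpy(dtype=np.int64),
            g["end"].to_numpy(dtype=np.int64),
            g["value"].to_numpy(dtype=float),
        )
        for c, g in track.sort_values(["chrom", "start"]).groupby("chrom")
    }
    out = {}
    for gene, row in loci.iterrows():
        lo = max(0, int(row["start"]) - flank)
        hi = int(row["end"]) + flank
        if int(row["end"]) <= int(row["start"]):
            raise ValueError(f"empty locus {gene!r}")
        if row["chrom"] not in by_chrom:
            out[gene] = 0.0
            continue
        s, e, v = by_chrom[row["chrom"]]
        out[gene] = _interval_mean(s, e, v, lo, hi)
    return pd.Series(out, name="density")


def tss_profile(
    fragment_ends: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 2000,
    n_cells: int | None = None,
    mean_depth: float | None = None,
) -> np.ndarray:
    """Per-base insertion profile around TSS, strand-aware and depth-scaled.

    ``fragment_ends``: frame (chrom, pos) of Tn5 insertion positions;
    ``tss``: frame (chrom, tss, strand).  Counts of insertions at offset
    d in [-window, window] from each TSS are summed over TSS (minus-strand
    profiles reversed) and divided by n_cells * mean_depth when both are
    given.  Returns a vector of length 2*window + 1 (center = TSS).
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    profile = np.zeros(2 * window + 1)
    ends_by_chrom = {c: np.sort(g["pos"].to_numpy(dtype=np.int64)) for c, g in fragment_ends.groupby("chrom")}
    for _, row in tss.iterrows():
        pos = ends_by_chrom.get(row["chrom"])
        if pos is None:
            continue
        center = int(row["tss"])
        lo = np.searchsorted(pos, center - window, side="left")
        hi = np.searchsorted(pos, center + window, side="right")
        offsets = pos[lo:hi] - center
        if row["strand"] == "-":
            offsets = -offsets
        np.add.at(profile, offsets + window, 1.0)
    if n_cells is not None and mean_depth is not None:
        profile = profile / (n_cells * mean_depth)
    return profile


def peak_proximity(
    peaks: pd.DataFrame, tss: pd.DataFrame, window: int = 20_000
) -> pd.DataFrame:
    """Per-gene peak count in the TSS window plus nearest-peak distance.

    A peak is counted when its midpoint lies in [TSS - window/2,
    TSS + window/2).  The nearest distance is 0 when the TSS falls inside a
    peak, otherwise the gap to the closest peak edge; +inf when the
    chromosome has no peaks.
    """
    half = window // 2
    by_chrom = {
        c: (g["start"].to_numpy(dtype=np.int64), g["end"].to_numpy(dtype=np.int64))
        for c, g in peaks.sort_values(["chrom", "start"]).groupby("chrom")
    }
    rows = {}
    for gene, row in tss.iterrows():
        chrom = row["chrom"]
        center = int(row["tss"])
        if chrom not in by_chrom:
            rows[gene] = (0, float("inf"))
            continue
        s, e = by_chrom[chrom]
        mid = (s + e) // 2
        count = int(np.sum((mid >= center - half) & (mid < center + half)))
        inside = (center >= s) & (center < e)
        if np.any(inside):
            dist = 0.0
        else:
            dist = float(np.min(np.minimum(np.abs(s - center), np.abs(e - center))))
        rows[gene] = (count, dist)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["peak_count", "nearest_distance"])
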