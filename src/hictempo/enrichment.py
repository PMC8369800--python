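"""Signal-track enrichment statistics over genomic region sets.

Fold enrichment (median in-region signal over genome-wide median signal),
Spearman correlation against a +-1 pseudo-cluster indicator, a Wilcoxon
rank-sum region-vs-rest test, and peak-density profiles around classed TAD
boundaries.  A bin belongs to a region set when it intersects any interval
(any-overlap rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import IntervalSet, SignalTrack

__all__ = [
    "EnrichmentReport",
    "bins_in_regions",
    "fold_enrichment",
    "pseudo_cluster_correlation",
    "region_vs_rest_test",
    "boundary_peak_density",
]


@dataclass
class EnrichmentReport:
    region_set: str
    fold_enrichment: float
    spearman_rho: float
    ranksum_p: float
    n_bins_in: int


def bins_in_regions(track: SignalTrack, regions: IntervalSet) -> np.ndarray:
    """Boolean per-bin membership: bin intersects any interval (same chrom)."""
    member = np.zeros(track.n_bins, dtype=bool)
    bs = track.bin_size
    for rec in regions.records.itertuples(index=False):
        if rec.chrom != track.chrom:
            continue
        first = int(rec.start) // bs
        last = (int(rec.end) - 1) // bs
        member[max(first, 0) : min(last + 1, track.n_bins)] = True
    return member


def fold_enrichment(track: SignalTrack, regions: IntervalSet) -> float:
    """Median in-region bin signal / median signal across all bins."""
    member = bins_in_regions(track, regions)
    if not member.any():
        raise ValueError("no bins overlap the region set")
    genome_med = float(np.median(track.values))
    if genome_med == 0:
        return float("nan")
    return float(np.median(track.values[member]) / genome_med)


def pseudo_cluster_correlation(track: SignalTrack, regions: IntervalSet) -> float:
    """Spearman rho between the binned signal and a +-1 region indicator."""
    member = bins_in_regions(track, regions)
    indicator = np.where(member, 1.0, -1.0)
    rho = stats.spearmanr(track.values, indicator).statistic
    return float(rho)


def region_vs_rest_test(track: SignalTrack, regions: IntervalSet) -> float:
    """Two-sided Wilcoxon rank-sum p: in-region bins vs all other bins."""
    member = bins_in_regions(track, regions)
    a = track.values[member]
    b = track.values[~member]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(stats.ranksums(a, b).pvalue)


def boundary_peak_density(
    peaks: IntervalSet,
    boundaries_by_class: dict[str, np.ndarray],
    flank_bins: int,
    bin_size: int,
    n_bins: int,
    chrom: str = "chrS",
) -> dict[str, np.ndarray]:
    """Mean peak count per bin at each offset around classed boundaries.

    ``boundaries_by_class`` maps a class name (unchanged/lost/gained) to
    boundary bin indices.  A peak contributes to every bin it overlaps.
    Profiles have length 2*flank_bins + 1 (offsets -flank..+flank).
    """
    peak_count = np.zeros(n_bins)
    for rec in peaks.records.itertuples(index=False):
        if rec.chrom != chrom:
            continue
        first = max(int(rec.start) // bin_size, 0)
        last = min((int(rec.end) - 1) // bin_size, n_bins - 1)
        peak_count[first : last + 1] += 1

    profiles = {}
    offsets = np.arange(-flank_bins, flank_bins + 1)
    for klass, bounds in boundaries_by_class.items():
        bounds = np.asarray(bounds, dtype=int)
        prof = np.zeros(offsets.size)
        if bounds.size:
            for k, off in enumerate(offsets):
                pos = bounds + off
                ok = (pos >= 0) & (pos < n_bins)
                prof[k] = peak_count[pos[ok]].mean() if ok.any() else 0.0
        profiles[klass] = prof
    return profiles
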