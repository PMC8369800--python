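"""A/B compartment analysis for a multi-timepoint Hi-C experiment.

PC1 is the leading eigenvector of the Pearson correlation matrix of the O/E
contact map, sign-oriented by a gene-density-like track (positive PC1 = A).
Downstream statistics: TAD-level smoothing, per-bin compartment strength
(same-type over cross-type mean O/E), saddle aggregation over PC1 quantiles,
mean interactions between PC1 ranges, interaction homogeneity (1/CV^2), run-
length compartment regions, and a timecourse switch classifier with
early/late-affected and recoverable/irrecoverable subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix, IntervalSet, SignalTrack
from .simulate import TIMEPOINT_ORDER, TREATED_TIMEPOINTS, EARLY_TIMEPOINTS

__all__ = [
    "CompartmentProfile",
    "SaddleResult",
    "SwitchClassification",
    "compute_pc1",
    "smooth_by_tads",
    "per_bin_strength",
    "classify_strength_change",
    "saddle",
    "interactions_by_pc1_range",
    "homogeneity",
    "compartment_regions",
    "region_size_stats",
    "classify_switch",
]


@dataclass
class CompartmentProfile:
    """Per-bin PC1, A/B label, and optional compartment strength."""

    chrom: str
    bin_size: int
    pc1: np.ndarray  # NaN at filtered bins
    labels: np.ndarray  # 'A' | 'B' | 'filtered'
    strength: np.ndarray | None = None
    timepoint: str = ""
    eig_fraction: float = np.nan  # leading-eigenvalue share; low => low confidence

    @property
    def n_bins(self) -> int:
        return self.pc1.size

    def a_bins(self) -> np.ndarray:
        return self.labels == "A"

    def b_bins(self) -> np.ndarray:
        return self.labels == "B"


def _labels_from_pc1(pc1: np.ndarray) -> np.ndarray:
    labels = np.where(pc1 > 0, "A", "B").astype(object)
    labels[np.isnan(pc1)] = "filtered"
    return labels


def compute_pc1(
    matrix: ContactMatrix,
    orientation_track: SignalTrack,
    oe: np.ndarray | None = None,
    timepoint: str = "",
) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson-correlation matrix.

    The sign is oriented so the correlation with ``orientation_track``
    (a gene-density-like signal, higher in active chromatin) is positive;
    positive PC1 is assigned to compartment A.  PC1 is rescaled so the 99th
    percentile of |PC1| equals 1, making fixed thresholds (0.4/0.5/0.8)
    meaningful across datasets.
    """
    from .matrix import oe_transform

    if oe is None:
        oe = oe_transform(matrix)
    keep = ~matrix.mask
    sub = oe[np.ix_(keep, keep)]
    # guard: bins with constant O/E rows make the correlation undefined
    sd = np.nanstd(sub, axis=1)
    good = sd > 0
    if good.sum() < 10:
        raise ValueError("degenerate correlation matrix: too few variable bins")
    keep_idx = np.flatnonzero(keep)[good]
    sub = sub[np.ix_(good, good)]
    sub = np.where(np.isnan(sub), 1.0, sub)
    corr = np.corrcoef(sub)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    eig_fraction = float(evals[-1] / np.abs(evals).sum())

    pc1 = np.full(matrix.n_bins, np.nan)
    pc1[keep_idx] = lead
    track = orientation_track.values
    valid = ~np.isnan(pc1)
    r = np.corrcoef(pc1[valid], track[valid])[0, 1]
    if r < 0:
        pc1 = -pc1
    q99 = np.nanquantile(np.abs(pc1), 0.99)
    if q99 > 0:
        pc1 = pc1 / q99
    return CompartmentProfile(
        matrix.chrom, matrix.bin_size, pc1, _labels_from_pc1(pc1),
        timepoint=timepoint, eig_fraction=eig_fraction,
    )


def smooth_by_tads(profile: CompartmentProfile, tads) -> CompartmentProfile:
    """Replace each bin's PC1 by the mean PC1 of its TAD; re-derive labels.

    ``tads`` is a :class:`~hictempo.tads.TADSet` (or any object with a
    ``domains`` list of (start, end) bin intervals tiling the chromosome).
    """
    pc1 = profile.pc1.copy()
    covered = np.zeros(profile.n_bins, dtype=bool)
    for s, e in tads.domains:
        seg = profile.pc1[s:e]
        if np.all(np.isnan(seg)):
            continue
        pc1[s:e] = np.nanmean(seg)
        covered[s:e] = True
    if not covered.all():
        import warnings

        warnings.warn("bins outside any TAD kept unsmoothed", stacklevel=2)
    pc1[np.isnan(profile.pc1)] = np.nan  # filtered bins stay filtered
    return CompartmentProfile(
        profile.chrom, profile.bin_size, pc1, _labels_from_pc1(pc1),
        timepoint=profile.timepoint, eig_fraction=profile.eig_fraction,
    )


# ---------------------------------------------------------------------------
# compartment strength


def per_bin_strength(oe: np.ndarray, profile: CompartmentProfile) -> np.ndarray:
    """Per-bin compartment strength: mean same-type O/E over mean cross-type.

    For a bin of type T, strength = mean(O/E to other T bins) / mean(O/E to
    opposite-type bins); NaN for filtered bins or bins lacking partners.
    """
    n = profile.n_bins
    strength = np.full(n, np.nan)
    a = profile.a_bins()
    b = profile.b_bins()
    for i in range(n):
        lab = profile.labels[i]
        if lab not in ("A", "B"):
            continue
        same = a.copy() if lab == "A" else b.copy()
        opp = b if lab == "A" else a
        same[i] = False
        same_vals = oe[i, same]
        opp_vals = oe[i, opp]
        same_vals = same_vals[~np.isnan(same_vals)]
        opp_vals = opp_vals[~np.isnan(opp_vals)]
        if same_vals.size == 0 or opp_vals.size == 0:
            continue
        denom = opp_vals.mean()
        if denom > 0:
            strength[i] = same_vals.mean() / denom
    return strength


def classify_strength_change(
    strength_t: np.ndarray, strength_0: np.ndarray, fold: float = 2.0
) -> dict[str, float]:
    """Proportions of strengthened / weakened / unchanged bins.

    A bin is strengthened when strength_t/strength_0 >= fold and weakened
    when <= 1/fold; proportions are over bins with valid strength at both
    timepoints.
    """
    valid = ~np.isnan(strength_t) & ~np.isnan(strength_0) & (strength_0 > 0)
    if not valid.any():
        raise ValueError("no bins with valid strength at both timepoints")
    ratio = strength_t[valid] / strength_0[valid]
    return {
        "strengthened": float(np.mean(ratio >= fold)),
        "weakened": float(np.mean(ratio <= 1.0 / fold)),
        "unchanged": float(np.mean((ratio > 1.0 / fold) & (ratio < fold))),
        "n": int(valid.sum()),
    }


# ---------------------------------------------------------------------------
# saddle


@dataclass
class SaddleResult:
    """Mean O/E between PC1 quantile groups, plus a corner-contrast score."""

    grid: np.ndarray  # (n, n), symmetric
    n_quantiles: int
    qrange: tuple[float, float]
    score: float  # mean(AA+BB corner cells) / mean(AB corner cells)


def saddle(
    oe: np.ndarray,
    pc1: np.ndarray,
    n: int = 50,
    qrange: tuple[float, float] = (0.005, 0.995),
    corner_frac: float = 0.2,
) -> SaddleResult:
    """Saddle aggregation of O/E over PC1 quantile groups.

    Bins with PC1 outside the ``qrange`` quantiles are trimmed; the rest are
    ranked into ``n`` equal-count groups (ascending PC1).  The corner score
    uses the extreme ``corner_frac`` of quantiles:
    mean(BB corner + AA corner) / mean(AB corners).
    """
    valid = ~np.isnan(pc1)
    vals = pc1[valid]
    if vals.size < n:
        raise ValueError("fewer non-masked bins than quantile groups")
    lo, hi = np.quantile(vals, qrange[0]), np.quantile(vals, qrange[1])
    keep = valid & (pc1 >= lo) & (pc1 <= hi)
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(pc1[idx], kind="stable")]
    groups = np.array_split(order, n)

    grid = np.full((n, n), np.nan)
    for a in range(n):
        ga = groups[a]
        for b in range(a, n):
            gb = groups[b]
            block = oe[np.ix_(ga, gb)]
            if a == b:
                m = np.ones_like(block, dtype=bool)
                np.fill_diagonal(m, False)
                block = block[m]
            vals_ab = block[~np.isnan(block)]
            if vals_ab.size:
                grid[a, b] = grid[b, a] = vals_ab.mean()

    k = max(1, int(round(n * corner_frac)))
    bb = grid[:k, :k]
    aa = grid[-k:, -k:]
    ab = grid[:k, -k:]
    num = np.nanmean(np.concatenate([aa.ravel(), bb.ravel()]))
    den = np.nanmean(ab)
    score = float(num / den) if den > 0 else np.nan
    return SaddleResult(grid, n, qrange, score)


def interactions_by_pc1_range(
    oe: np.ndarray,
    profile: CompartmentProfile,
    ranges: list[tuple[float, float]],
) -> np.ndarray:
    """Mean O/E between groups of bins defined by disjoint PC1 intervals.

    Interval (lo, hi] is half-open on the left, matching range definitions
    like "0.2 < PC1 <= 0.4".  Cell (p, q) is the mean O/E over bin pairs
    (i != j) with PC1 in range p and q; NaN for empty ranges.
    """
    for a in range(len(ranges)):
        for b in range(a + 1, len(ranges)):
            lo = max(ranges[a][0], ranges[b][0])
            hi = min(ranges[a][1], ranges[b][1])
            if lo < hi:
                raise ValueError("PC1 ranges must be disjoint")
    members = [
        np.flatnonzero((profile.pc1 > lo) & (profile.pc1 <= hi)) for lo, hi in ranges
    ]
    m = len(ranges)
    grid = np.full((m, m), np.nan)
    for p in range(m):
        for q in range(p, m):
            gp, gq = members[p], members[q]
            if gp.size == 0 or gq.size == 0:
                continue
            block = oe[np.ix_(gp, gq)]
            if p == q:
                mask = np.ones_like(block, dtype=bool)
                np.fill_diagonal(mask, False)
                block = block[mask]
            vals = block[~np.isnan(block)]
            if vals.size:
                grid[p, q] = grid[q, p] = vals.mean()
    return grid


def homogeneity(group_means: np.ndarray) -> float:
    """Reciprocal of CV^2 of group-mean interactions: mean^2 / sample var.

    All-equal input has zero variance and returns +inf.
    """
    v = np.asarray(group_means, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need >= 2 group means")
    mu = v.mean()
    if mu <= 0:
        raise ValueError("group means must have positive mean")
    var = v.var(ddof=1)
    if var == 0:
        return float("inf")
    return float(mu**2 / var)


def aa_decile_means(oe: np.ndarray, profile: CompartmentProfile, n_groups: int = 10) -> np.ndarray:
    """Mean A-A O/E between PC1 deciles within compartment A.

    The within-A decile-pair means are the input to :func:`homogeneity`.
    Returns the flattened upper triangle (incl. diagonal) of the decile grid.
    """
    a_idx = np.flatnonzero(profile.a_bins())
    if a_idx.size < n_groups:
        raise ValueError("too few A bins for decile grouping")
    order = a_idx[np.argsort(profile.pc1[a_idx], kind="stable")]
    groups = np.array_split(order, n_groups)
    means = []
    for p in range(n_groups):
        for q in range(p, n_groups):
            block = oe[np.ix_(groups[p], groups[q])]
            if p == q:
                m = np.ones_like(block, dtype=bool)
                np.fill_diagonal(m, False)
                block = block[m]
            vals = block[~np.isnan(block)]
            if vals.size:
                means.append(vals.mean())
    return np.asarray(means)


# ---------------------------------------------------------------------------
# compartment regions and switch classification


def compartment_regions(profile: CompartmentProfile) -> IntervalSet:
    """Maximal runs of identical labels as BED intervals (bp coordinates)."""
    labels = profile.labels
    bs = profile.bin_size
    recs = []
    start = 0
    for i in range(1, profile.n_bins + 1):
        if i == profile.n_bins or labels[i] != labels[start]:
            recs.append((profile.chrom, start * bs, i * bs, str(labels[start])))
            start = i
    return IntervalSet(pd.DataFrame(recs, columns=["chrom", "start", "end", "name"]))


def region_size_stats(regions: IntervalSet, label: str | None = None) -> tuple[float, float]:
    """(mean region size, total length) in bp, optionally for one label."""
    df = regions.records
    if label is not None:
        df = df[df["name"] == label]
    if df.empty:
        return float("nan"), 0.0
    sizes = (df["end"] - df["start"]).to_numpy(dtype=float)
    return float(sizes.mean()), float(sizes.sum())


@dataclass
class SwitchRegion:
    start_bin: int
    end_bin: int
    label: str  # 'constant A' | 'constant B' | 'switch' | 'filtered'
    subtype: str = ""  # 'early-affected,recoverable' etc., switch only
    states: dict = field(default_factory=dict)  # timepoint -> 'A'/'B'


@dataclass
class SwitchClassification:
    regions: list[SwitchRegion]
    proportions: dict[str, float]
    low_pc1_overlap_p: float  # hypergeometric enrichment of switch in low-PC1
    bin_size: int

    def regions_with(self, label: str) -> list[SwitchRegion]:
        return [r for r in self.regions if r.label == label]

    def region_at(self, bin_index: int) -> SwitchRegion:
        for r in self.regions:
            if r.start_bin <= bin_index < r.end_bin:
                return r
        raise KeyError(bin_index)


def classify_switch(
    profiles: dict[str, CompartmentProfile],
    low_pc1: tuple[float, float] = (-0.5, 0.5),
) -> SwitchClassification:
    """Classify compartment state trajectories over the treatment timecourse.

    Timepoints must include the canonical set {0,1,2,5,10,30,withdrawal}.
    Bins filtered at any timepoint are 'filtered'.  Regions are maximal runs
    of bins sharing an identical label trajectory.  A region is constant if
    its label at every treated timepoint (1..30) equals its label at 0;
    otherwise it is a switch region, early-affected if the first change is at
    1/2/5 and late-affected if at 10/30, recoverable iff the withdrawal label
    equals the 0-min label.  Also reports a hypergeometric upper-tail p for
    the overlap of switch bins with low-PC1 (at 0 min) bins.
    """
    for tp in TIMEPOINT_ORDER:
        if tp not in profiles:
            raise ValueError(f"missing timepoint {tp!r}")
    n = profiles["0"].n_bins
    lab = {tp: profiles[tp].labels for tp in TIMEPOINT_ORDER}
    filtered = np.zeros(n, dtype=bool)
    for tp in TIMEPOINT_ORDER:
        filtered |= lab[tp] == "filtered"

    # per-bin trajectory key
    keys = np.empty(n, dtype=object)
    for i in range(n):
        keys[i] = "F" if filtered[i] else "".join(lab[tp][i] for tp in TIMEPOINT_ORDER)

    regions: list[SwitchRegion] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or keys[i] != keys[start]:
            regions.append(_classify_region(start, i, keys[start], lab))
            start = i

    # proportions by bin
    n_bins_by = {"constant A": 0, "constant B": 0, "switch": 0, "filtered": 0}
    for r in regions:
        n_bins_by[r.label] += r.end_bin - r.start_bin
    proportions = {k: v / n for k, v in n_bins_by.items()}

    # hypergeometric enrichment of switch bins in low-PC1 bins (at 0 min)
    pc1_0 = profiles["0"].pc1
    population = ~filtered
    low = population & (pc1_0 > low_pc1[0]) & (pc1_0 < low_pc1[1])
    switch_bins = np.zeros(n, dtype=bool)
    for r in regions:
        if r.label == "switch":
            switch_bins[r.start_bin : r.end_bin] = True
    M = int(population.sum())
    K = int(low.sum())
    N = int(switch_bins.sum())
    k = int((switch_bins & low).sum())
    p = float(stats.hypergeom.sf(k - 1, M, K, N)) if N > 0 else 1.0

    return SwitchClassification(regions, proportions, p, profiles["0"].bin_size)


def _classify_region(start: int, end: int, key: str, lab: dict) -> SwitchRegion:
    if key == "F":
        return SwitchRegion(start, end, "filtered")
    states = {tp: key[i] for i, tp in enumerate(TIMEPOINT_ORDER)}
    base = states["0"]
    changed_at = [tp for tp in TREATED_TIMEPOINTS if states[tp] != base]
    if not changed_at:
        return SwitchRegion(start, end, f"constant {base}", states=states)
    onset = "early-affected" if changed_at[0] in EARLY_TIMEPOINTS else "late-affected"
    rec = "recoverable" if states["withdrawal"] == base else "irrecoverable"
    return SwitchRegion(start, end, "switch", f"{onset},{rec}", states)
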