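"""Significant chromatin interactions between TADs and their aggregation.

Contacts are aggregated over TAD pairs; each distal pair gets an upper-tail
hypergeometric p-value given its marginal totals and the grand total, BH
correction across pairs, and an observed/expected filter against the
distance-decay background.  Calls are classed by overlap of both anchors
with top-decile (condensate-enriched), bottom-decile (condensate-absent), or
randomly sampled (random) signal bins, and summarized by aggregate peak
analysis (APA) windows on the O/E map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix, SignalTrack
from .tads import TADSet

__all__ = [
    "InteractionCall",
    "APAResult",
    "TADPairTable",
    "aggregate_tad_pairs",
    "call_significant",
    "classify_by_signal",
    "distance_distribution",
    "apa",
]


@dataclass
class InteractionCall:
    """One TAD-pair (or anchor-pair) interaction record."""

    anchor_a: tuple[int, int]  # bin interval [start, end)
    anchor_b: tuple[int, int]
    observed: float
    expected: float
    oe: float
    p: float
    fdr: float
    klass: str = "none"  # 'enriched' | 'absent' | 'random' | 'none'
    bin_size: int = 40_000

    @property
    def distance(self) -> float:
        """Midpoint-to-midpoint distance in bp."""
        mid_a = 0.5 * (self.anchor_a[0] + self.anchor_a[1]) * self.bin_size
        mid_b = 0.5 * (self.anchor_b[0] + self.anchor_b[1]) * self.bin_size
        return abs(mid_b - mid_a)

    @property
    def anchor_mid_bins(self) -> tuple[int, int]:
        return (
            (self.anchor_a[0] + self.anchor_a[1] - 1) // 2,
            (self.anchor_b[0] + self.anchor_b[1] - 1) // 2,
        )


@dataclass
class TADPairTable:
    """Aggregated TAD-pair counts with marginals for the hypergeometric test."""

    domains: list[tuple[int, int]]
    observed: np.ndarray  # (n_tads, n_tads) upper-triangle-symmetric
    marginals: np.ndarray  # per-TAD total counts
    grand_total: float
    bin_size: int
    decay: np.ndarray  # mean raw count per bin-pair distance


def aggregate_tad_pairs(matrix: ContactMatrix, tads: TADSet) -> TADPairTable:
    """Aggregate raw contacts over TAD pairs; retain marginals and decay.

    observed(p, q) sums counts over unordered bin pairs (i in p, j in q);
    the sum over all p <= q equals the matrix total.
    """
    domains = tads.domains
    n_t = len(domains)
    tad_id = np.empty(matrix.n_bins, dtype=int)
    for t, (s, e) in enumerate(domains):
        tad_id[s:e] = t
    counts = matrix.counts
    iu, ju = np.triu_indices(matrix.n_bins)
    vals = counts[iu, ju]
    obs = np.zeros((n_t, n_t))
    np.add.at(obs, (tad_id[iu], tad_id[ju]), vals)
    obs = np.triu(obs) + np.triu(obs, 1).T

    # per-distance decay background: median (robust to focal enrichment),
    # falling back to the mean where the median is zero
    n = matrix.n_bins
    decay = np.zeros(n)
    for k in range(n):
        diag = np.diagonal(counts, offset=k)
        med = np.median(diag)
        decay[k] = med if med > 0 else diag.mean()

    marginals = obs.sum(axis=1)  # total contacts involving each TAD
    grand = float(np.triu(obs).sum())
    return TADPairTable(domains, obs, marginals, grand, matrix.bin_size, decay)


def call_significant(
    table: TADPairTable,
    fdr_thresh: float = 0.01,
    min_oe: float = 10.0,
    min_separation_tads: int = 1,
) -> tuple[list[InteractionCall], pd.DataFrame]:
    """Hypergeometric significant-interaction calling over distal TAD pairs.

    The expected count of a pair comes from the distance-decay background
    aggregated at TAD-pair level (scaled to the tested total); the p-value is
    the upper tail of a central hypergeometric with the pair's marginal
    totals and the grand total; BH across tested pairs.  Calls require
    FDR < ``fdr_thresh`` and O/E >= ``min_oe``.  Returns the calls plus the
    full tested table.
    """
    if table.grand_total <= 0:
        raise ValueError("zero grand total")
    domains = table.domains
    n_t = len(domains)
    rows = []
    for p in range(n_t):
        for q in range(p + min_separation_tads, n_t):
            sp, ep = domains[p]
            sq, eq = domains[q]
            exp_pairs = 0.0
            for i in range(sp, ep):
                seps = np.arange(sq, eq) - i
                exp_pairs += table.decay[np.abs(seps)].sum()
            rows.append((p, q, table.observed[p, q], exp_pairs))
    df = pd.DataFrame(rows, columns=["p", "q", "observed", "expected_raw"])
    # scale expected so totals match over tested pairs
    scale = df["observed"].sum() / df["expected_raw"].sum()
    df["expected"] = df["expected_raw"] * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        df["oe"] = df["observed"] / df["expected"]

    M = int(round(table.grand_total))
    pvals = np.empty(len(df))
    for k, row in enumerate(df.itertuples(index=False)):
        n_a = int(round(table.marginals[row.p]))
        n_b = int(round(table.marginals[row.q]))
        n_a, n_b = min(n_a, M), min(n_b, M)
        pvals[k] = stats.hypergeom.sf(int(round(row.observed)) - 1, M, n_a, n_b)
    df["pval"] = pvals
    df["fdr"] = stats.false_discovery_control(pvals)

    calls = []
    for row in df.itertuples(index=False):
        if row.fdr < fdr_thresh and row.oe >= min_oe:
            calls.append(
                InteractionCall(
                    domains[row.p], domains[row.q], float(row.observed),
                    float(row.expected), float(row.oe), float(row.pval),
                    float(row.fdr), bin_size=table.bin_size,
                )
            )
    return calls, df


# ---------------------------------------------------------------------------
# condensate classes


def _overlap_any(anchor: tuple[int, int], bins: np.ndarray) -> bool:
    s, e = anchor
    return bool(bins[s:e].any())


def classify_by_signal(
    calls: list[InteractionCall],
    track: SignalTrack,
    top_q: float = 0.10,
    seed: int = 0,
) -> list[InteractionCall]:
    """Assign condensate classes from a binned signal track.

    enriched: both anchors overlap >= 1 top-decile bin; absent: both overlap
    bottom-decile bins; random: both overlap a seeded uniform 10% bin sample.
    Precedence enriched > absent > random; quantile ties broken by bin index.
    """
    v = track.values
    n = v.size
    if np.allclose(v, v[0]):
        raise ValueError("non-informative track: constant signal")
    k = max(1, int(round(top_q * n)))
    order = np.lexsort((np.arange(n), v))  # ascending value, ties by index
    bottom = np.zeros(n, dtype=bool)
    bottom[order[:k]] = True
    top = np.zeros(n, dtype=bool)
    top[order[-k:]] = True
    rng = np.random.default_rng(seed)
    rand = np.zeros(n, dtype=bool)
    rand[rng.choice(n, size=k, replace=False)] = True

    out = []
    for c in calls:
        if _overlap_any(c.anchor_a, top) and _overlap_any(c.anchor_b, top):
            klass = "enriched"
        elif _overlap_any(c.anchor_a, bottom) and _overlap_any(c.anchor_b, bottom):
            klass = "absent"
        elif _overlap_any(c.anchor_a, rand) and _overlap_any(c.anchor_b, rand):
            klass = "random"
        else:
            klass = "none"
        out.append(
            InteractionCall(
                c.anchor_a, c.anchor_b, c.observed, c.expected, c.oe, c.p, c.fdr,
                klass, c.bin_size,
            )
        )
    return out


def distance_distribution(
    calls: list[InteractionCall],
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """Per-class anchor-midpoint distances and pairwise rank-sum p-values."""
    by_class: dict[str, list[float]] = {}
    for c in calls:
        by_class.setdefault(c.klass, []).append(c.distance)
    dists = {k: np.asarray(v) for k, v in by_class.items()}
    pvals: dict[tuple[str, str], float] = {}
    names = sorted(dists)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            if np.array_equal(np.sort(dists[a]), np.sort(dists[b])):
                pvals[(a, b)] = 1.0
            else:
                pvals[(a, b)] = float(stats.ranksums(dists[a], dists[b]).pvalue)
    return dists, pvals


# ---------------------------------------------------------------------------
# aggregate peak analysis


@dataclass
class APAResult:
    """Mean O/E window around anchor pairs."""

    window: np.ndarray  # (2k+1, 2k+1)
    center_score: float  # mean of the central 3x3 cells
    n_aggregated: int
    n_filtered: int
    resolution: int

    def corner_score(self, c: int = 3) -> float:
        """Mean of the four c x c corner blocks (background level)."""
        w = self.window
        blocks = [w[:c, :c], w[:c, -c:], w[-c:, :c], w[-c:, -c:]]
        return float(np.nanmean(np.concatenate([b.ravel() for b in blocks])))


def apa(
    oe: np.ndarray,
    anchor_pairs: list[tuple[int, int]],
    resolution: int = 40_000,
    k: int = 10,
) -> APAResult:
    """Aggregate peak analysis: mean O/E over (2k+1)^2 windows at anchors.

    Pairs closer than 2k+1 bins to the matrix edge or the diagonal are
    filtered (their count is reported).  The center score is the mean of the
    central 3x3 cells (offsets < 3 bins from the center).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = oe.shape[0]
    w = 2 * k + 1
    acc = np.zeros((w, w))
    cnt = np.zeros((w, w))
    used = 0
    filtered = 0
    for i, j in anchor_pairs:
        if i > j:
            i, j = j, i
        if i - k < 0 or j + k >= n or (j - k) - (i + k) < 1:
            filtered += 1
            continue
        win = oe[i - k : i + k + 1, j - k : j + k + 1]
        ok = ~np.isnan(win)
        acc[ok] += win[ok]
        cnt[ok] += 1
        used += 1
    if used == 0:
        raise ValueError(f"no eligible anchor pairs after edge filtering ({filtered} filtered)")
    with np.errstate(invalid="ignore"):
        window = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    center = window[k - 1 : k + 2, k - 1 : k + 2]
    return APAResult(window, float(np.nanmean(center)), used, filtered, resolution)
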