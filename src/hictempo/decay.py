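"""Distance-decay statistics: relative contact probability and change counts.

RCP (relative contact probability) is the mean balanced contact per bin pair
in log-spaced genomic-distance strata, normalized so the curve sums to one;
it is therefore invariant to sequencing depth.  Fold changes versus the
untreated baseline are summarized across chromosomes with a paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ContactMatrix

__all__ = [
    "RCPCurve",
    "rcp",
    "rcp_fold_change",
    "changed_fraction",
    "DISTANCE_RESOLUTION_MAP",
]

#: Distance -> matrix resolution used for changed-interaction quantification.
#: The source protocol lists "1 Mb" for two different resolutions; the first
#: entry is interpreted as 100 Mb (500 kb matrices) — see docs/methods.md.
DISTANCE_RESOLUTION_MAP = {
    100_000_000: 500_000,
    10_000_000: 100_000,
    1_000_000: 40_000,
    100_000: 25_000,
}


@dataclass
class RCPCurve:
    """Relative contact probability on log-spaced distance strata."""

    centers: np.ndarray  # stratum centers, bp (geometric mean of edges)
    values: np.ndarray  # normalized to sum to 1
    edges: np.ndarray  # stratum edges, bp
    chrom: str


def rcp(matrix: ContactMatrix, log_bins_per_decade: int = 8) -> RCPCurve:
    """Relative contact probability of a balanced matrix.

    Per stratum: sum of balanced contacts over non-masked pairs divided by
    the number of such pairs, then normalized to total 1.  The diagonal is
    excluded.
    """
    bal = matrix.balanced()
    n = matrix.n_bins
    dmin, dmax = matrix.bin_size, (n - 1) * matrix.bin_size
    n_strata = int(np.ceil(np.log10(dmax / dmin) * log_bins_per_decade))
    if n_strata < 2:
        raise ValueError("matrix too small for >= 2 distance strata")
    edges = np.geomspace(dmin, dmax * (1 + 1e-9), n_strata + 1)

    means = np.full(n_strata, np.nan)
    # accumulate per-diagonal sums into strata
    sums = np.zeros(n_strata)
    counts = np.zeros(n_strata)
    for k in range(1, n):
        diag = np.diagonal(bal, offset=k)
        valid = ~np.isnan(diag)
        if not valid.any():
            continue
        s = np.searchsorted(edges, k * matrix.bin_size, side="right") - 1
        s = min(max(s, 0), n_strata - 1)
        sums[s] += diag[valid].sum()
        counts[s] += valid.sum()
    if int((counts > 0).sum()) < 2:
        raise ValueError("matrix too small for >= 2 populated distance strata")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    total = np.nansum(means)
    values = means / total
    centers = np.sqrt(edges[:-1] * edges[1:])
    return RCPCurve(centers, values, edges, matrix.chrom)


@dataclass
class FoldChangeResult:
    """Per-chromosome log2 RCP fold change at one distance."""

    distance: float
    log2_fc: np.ndarray  # one value per chromosome
    mean: float
    sd: float
    p_value: float


def rcp_fold_change(
    curves_t: dict[str, RCPCurve], curves_0: dict[str, RCPCurve], distance: float
) -> FoldChangeResult:
    """log2(RCP_t / RCP_0) at the stratum containing ``distance``, per
    chromosome, with a paired t test across chromosomes (against zero)."""
    if set(curves_t) != set(curves_0):
        raise ValueError("chromosome sets differ between conditions")
    fcs = []
    for chrom in sorted(curves_t):
        ct, c0 = curves_t[chrom], curves_0[chrom]
        if not (ct.edges[0] <= distance <= ct.edges[-1]):
            raise ValueError(f"distance {distance} outside computed range for {chrom}")
        s = np.searchsorted(ct.edges, distance, side="right") - 1
        s = min(max(s, 0), len(ct.values) - 1)
        fcs.append(np.log2(ct.values[s] / c0.values[s]))
    fcs = np.asarray(fcs)
    if np.allclose(fcs, 0.0) or fcs.size < 2:
        p = 1.0
    else:
        p = float(stats.ttest_1samp(fcs, 0.0).pvalue)
        if np.isnan(p):
            p = 1.0
    sd = float(fcs.std(ddof=1)) if fcs.size > 1 else 0.0
    return FoldChangeResult(distance, fcs, float(fcs.mean()), sd, p)


def changed_fraction(
    matrix_t: ContactMatrix,
    replicates_0: tuple[ContactMatrix, ContactMatrix],
    distance: float,
) -> tuple[float, float]:
    """Fractions of bin pairs at a given distance above/below the baseline.

    Every non-masked bin pair at separation ``distance`` in the treated
    balanced matrix is compared with the mean balanced value of the two
    untreated replicates at the same pair.  Exact ties count as unchanged.
    """
    k = int(round(distance / matrix_t.bin_size))
    if not (1 <= k < matrix_t.n_bins):
        raise ValueError("no bin pairs at that distance")
    vt = np.diagonal(matrix_t.balanced(), offset=k)
    v0 = np.mean(
        [np.diagonal(r.balanced(), offset=k) for r in replicates_0], axis=0
    )
    valid = ~np.isnan(vt) & ~np.isnan(v0)
    if not valid.any():
        raise ValueError("no valid pairs at that distance")
    vt, v0 = vt[valid], v0[valid]
    inc = float(np.mean(vt > v0))
    dec = float(np.mean(vt < v0))
    return inc, dec
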