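"""Contact-matrix data model, text I/O, depth normalization, ICE balancing, O/E.

All analyses in this package are cis (one chromosome at a time) and operate on
symmetric binned contact matrices.  Coordinates are 0-based half-open BED
convention: bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "SignalTrack",
    "IntervalSet",
    "read_triplets",
    "write_triplets",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "downsample_to_min",
    "ice_balance",
    "oe_transform",
    "expected_by_distance",
]


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    bin_size : int
        Bin width in bp.
    counts : ndarray (n_bins, n_bins)
        Symmetric non-negative matrix.  Raw counts are integer-valued but
        stored as float64 so balanced matrices share the container.
    weights : ndarray (n_bins,) or None
        Multiplicative balancing weights ``w`` with balanced value
        ``m_ij = counts_ij * w_i * w_j`` (cooler convention, ``w = 1/b``).
        NaN at masked bins.  None until :func:`ice_balance` is applied.
    mask : ndarray of bool (n_bins,)
        True marks an excluded (low-coverage) bin.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def total(self) -> float:
        """Total pair count: sum over the upper triangle including diagonal."""
        return float(np.triu(self.counts).sum())

    def balanced(self) -> np.ndarray:
        """Balanced matrix ``counts_ij * w_i * w_j`` with NaN at masked bins."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_balance first")
        w = self.weights
        out = self.counts * w[:, None] * w[None, :]
        return out

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom,
            self.bin_size,
            self.counts.copy(),
            None if self.weights is None else self.weights.copy(),
            self.mask.copy(),
        )


@dataclass
class SignalTrack:
    """Per-bin non-negative signal (e.g. binned ChIP-seq coverage)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class IntervalSet:
    """BED-style intervals: (chrom, start, end, label), 0-based half-open."""

    records: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end"]
        for c in req:
            if c not in self.records.columns:
                raise ValueError(f"missing column {c!r}")
        if "name" not in self.records.columns:
            self.records = self.records.assign(name=".")
        if (self.records["start"] >= self.records["end"]).any():
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_arrays(
        cls, chrom: Iterable, start: Iterable, end: Iterable, name: Iterable | None = None
    ) -> "IntervalSet":
        df = pd.DataFrame({"chrom": list(chrom), "start": list(start), "end": list(end)})
        if name is not None:
            df["name"] = list(name)
        return cls(df)


# ---------------------------------------------------------------------------
# text I/O


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_triplets(path, n_bins: int, chrom: str = "chrS", bin_size: int = 40_000) -> ContactMatrix:
    """Read a sparse triplet file ``bin_i<TAB>bin_j<TAB>count``.

    Lower-triangle entries are mirrored to a symmetric matrix.  Malformed
    lines raise a ``ValueError`` naming the line number.
    """
    counts = np.zeros((n_bins, n_bins), dtype=np.float64)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed triplet at line {lineno}: {line!r}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValueError(f"{path}: bin index out of range at line {lineno}")
            if c < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    return ContactMatrix(chrom, bin_size, counts)


def write_triplets(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as triplet text; .gz honoured."""
    iu, ju = np.nonzero(np.triu(matrix.counts))
    vals = matrix.counts[iu, ju]
    with _open_text(path, "wt") as fh:
        for i, j, c in zip(iu, ju, vals):
            c = int(c) if float(c).is_integer() else c
            fh.write(f"{i}\t{j}\t{c}\n")


def write_bin_table(matrix_or_track, path) -> None:
    """Write the bin table (chrom, start, end) as BED."""
    obj = matrix_or_track
    with open(path, "w") as fh:
        for i in range(obj.n_bins):
            fh.write(f"{obj.chrom}\t{i * obj.bin_size}\t{(i + 1) * obj.bin_size}\n")


def read_bedgraph(path, chrom: str | None = None) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if df.empty:
        raise ValueError(f"{path}: no records" + (f" for {chrom}" if chrom else ""))
    bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    n_bins = int(df["end"].max() // bin_size)
    values = np.zeros(n_bins)
    idx = (df["start"] // bin_size).to_numpy()
    values[idx] = df["value"].to_numpy()
    return SignalTrack(str(df["chrom"].iloc[0]), bin_size, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.6g}\n")


def read_bed(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.records.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# depth normalization


def downsample_to_min(
    matrices: Sequence[ContactMatrix], seed: int | np.random.Generator = 0
) -> list[ContactMatrix]:
    """Randomly subsample every matrix to the smallest total pair count.

    Pairs are sampled without replacement (multivariate hypergeometric
    thinning of the upper-triangle counts), emulating random subsampling of
    valid pairs to the smallest library across replicates.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 matrices to harmonize depth")
    totals = [int(round(m.total())) for m in matrices]
    if min(totals) == 0:
        raise ValueError("empty matrix cannot be downsampled")
    target = min(totals)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for m, tot in zip(matrices, totals):
        if tot == target:
            out.append(m.copy())
            continue
        iu, ju = np.triu_indices(m.n_bins)
        colors = np.rint(m.counts[iu, ju]).astype(np.int64)
        kept = rng.multivariate_hypergeometric(colors, target, method="marginals")
        counts = np.zeros_like(m.counts)
        counts[iu, ju] = kept
        counts = counts + np.triu(counts, 1).T
        out.append(ContactMatrix(m.chrom, m.bin_size, counts, mask=m.mask.copy()))
    return out


def merge_replicates(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Sum replicate count matrices on a shared bin table."""
    base = matrices[0]
    counts = np.sum([m.counts for m in matrices], axis=0)
    return ContactMatrix(base.chrom, base.bin_size, counts)


# ---------------------------------------------------------------------------
# ICE balancing


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    mask_quantile: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: equalize non-masked row sums.

    Bins with zero coverage, or row sum below the ``mask_quantile`` quantile
    of nonzero row sums, are masked and excluded.  Iterates
    ``b_i <- b_i * s_i / mean(s)`` on the rescaled matrix until
    ``max_i |s_i/mean(s) - 1| < tol``.
    """
    counts = matrix.counts
    if not np.any(counts):
        raise ValueError("all-zero matrix cannot be balanced")
    rowsum = counts.sum(axis=1)
    nz = rowsum[rowsum > 0]
    thresh = np.quantile(nz, mask_quantile)
    mask = (rowsum == 0) | (rowsum < thresh) | matrix.mask
    keep = ~mask

    sub = counts[np.ix_(keep, keep)]
    b = np.ones(sub.shape[0])
    for _ in range(max_iter):
        s = (sub / b[:, None] / b[None, :]).sum(axis=1)
        rel = s / s.mean()
        if np.max(np.abs(rel - 1.0)) < tol:
            break
        b *= rel

    weights = np.full(matrix.n_bins, np.nan)
    # normalize so the balanced matrix keeps the original total scale
    bal_sub = sub / b[:, None] / b[None, :]
    scale = np.sqrt(sub.sum() / bal_sub.sum())
    weights[keep] = 1.0 / (b * scale) if scale > 0 else 1.0 / b
    out = matrix.copy()
    out.weights = weights
    out.mask = mask
    return out


# ---------------------------------------------------------------------------
# observed / expected


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean balanced contact per genomic-distance stratum.

    Returns ``d`` of length n_bins with ``d[k]`` the mean over all non-masked
    bin pairs at separation ``k``; NaN where no valid pair exists.
    """
    bal = matrix.balanced()
    n = matrix.n_bins
    d = np.full(n, np.nan)
    for k in range(n):
        diag = np.diagonal(bal, offset=k)
        valid = ~np.isnan(diag)
        if valid.any():
            d[k] = diag[valid].mean()
    return d


def oe_transform(matrix: ContactMatrix) -> np.ndarray:
    """Observed/expected matrix: balanced value over the per-distance mean.

    NaN at masked bins and at distances with no valid pairs.  By construction
    the mean of O/E over every distance stratum with valid pairs is 1.
    """
    bal = matrix.balanced()
    d = expected_by_distance(matrix)
    n = matrix.n_bins
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = bal / d[idx]
    return oe
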