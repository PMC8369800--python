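"""Synthetic multi-timepoint Hi-C experiment with planted ground truth.

The generator emulates the statistical structure of a binned cis Hi-C contact
map: power-law distance decay ``P(s) ~ s^-alpha``, a checkerboard compartment
signal driven by a planted per-bin eigenprofile ``e_i`` through
``exp(c * e_i * e_j)``, multiplicative intra-TAD enrichment, focal loop
anchors, and replicate-level Poisson counting noise.  A timecourse schedule
perturbs the baseline map per timepoint (long-range attenuation, compartment
amplitude scaling, boundary edits, compartment sign flips) so every
downstream statistic has a known planted answer.

Auxiliary generators produce compartment-correlated signal tracks, CSR and
Thomas-clustered 2-D point patterns, and Brownian particle trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .matrix import ContactMatrix, SignalTrack

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "TimepointSpec",
    "default_timepoints",
    "simulate_contact_map",
    "simulate_timecourse",
    "simulate_signal_track",
    "simulate_point_pattern",
    "simulate_trajectories",
    "PointPattern",
    "TrajectorySet",
]

TIMEPOINT_ORDER = ("0", "1", "2", "5", "10", "30", "withdrawal")
TREATED_TIMEPOINTS = ("1", "2", "5", "10", "30")
EARLY_TIMEPOINTS = ("1", "2", "5")
LATE_TIMEPOINTS = ("10", "30")


@dataclass
class SimConfig:
    """Parameters of the planted Hi-C generative model.

    depth is the expected total pair count per replicate; boosts are
    multiplicative (>= 1); decay_exponent is alpha in lambda ~ s^-alpha.
    """

    n_bins: int = 500
    bin_size: int = 40_000
    decay_exponent: float = 1.0
    compartment_amplitude: float = 1.0
    tad_boost: float = 3.0
    loop_boost: float = 3.0
    depth: float = 2_000_000.0
    n_replicates: int = 2
    seed: int = 0
    mean_tad_bins: int = 12
    mean_segment_tads: int = 2
    n_loops: int = 12
    long_range_cutoff_bins: int = 250  # 10 Mb at 40 kb

    def __post_init__(self) -> None:
        if self.n_bins < 50:
            raise ValueError("n_bins must be >= 50")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if min(self.tad_boost, self.loop_boost) < 1:
            raise ValueError("boosts must be >= 1")
        if self.compartment_amplitude < 0:
            raise ValueError("compartment_amplitude must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth emitted by the simulator."""

    true_profile: np.ndarray
    true_boundaries: np.ndarray  # strictly increasing, in (0, n_bins)
    loop_anchors: list[tuple[int, int]]
    switch_labels: dict = field(default_factory=dict)  # region -> planted label
    perturbation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = np.asarray(self.true_boundaries, dtype=int)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] < 1):
            raise ValueError("boundaries must be strictly increasing and >= 1")
        self.true_boundaries = b
        for i, j in self.loop_anchors:
            if not i < j:
                raise ValueError("loop anchors must satisfy i < j")

    def domains(self, n_bins: int) -> list[tuple[int, int]]:
        """TAD intervals [start, end) implied by the planted boundaries."""
        edges = [0, *self.true_boundaries.tolist(), n_bins]
        return [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]

    def to_json(self) -> str:
        d = {
            "true_profile": self.true_profile.tolist(),
            "true_boundaries": self.true_boundaries.tolist(),
            "loop_anchors": [list(p) for p in self.loop_anchors],
            "switch_labels": {str(k): v for k, v in self.switch_labels.items()},
            "perturbation_params": self.perturbation_params,
        }
        return json.dumps(d, indent=1)


@dataclass
class TimepointSpec:
    """Per-timepoint perturbation of the baseline generative model.

    long_range_attenuation multiplies lambda at separations beyond the
    config's long-range cutoff and shrinks the loop-boost excess of
    long-range anchors by the same factor (1.0 = no change).
    amplitude_multiplier scales compartment_amplitude.  boundary_deletions /
    boundary_insertions edit the planted TAD boundary set.  switch_regions
    are (start_bin, end_bin) intervals whose profile sign is flipped.
    """

    name: str
    long_range_attenuation: float = 1.0
    amplitude_multiplier: float = 1.0
    boundary_deletions: tuple = ()
    boundary_insertions: tuple = ()
    switch_regions: tuple = ()  # ((start, end), ...)


def default_timepoints() -> list[TimepointSpec]:
    """An identity timecourse over the canonical 7 timepoints."""
    return [TimepointSpec(name) for name in TIMEPOINT_ORDER]


# ---------------------------------------------------------------------------
# planted structure


def _plant_structure(config: SimConfig, rng: np.random.Generator) -> PlantedTruth:
    """Draw TAD boundaries, a TAD-aligned compartment profile, and loops."""
    n = config.n_bins
    # TAD boundaries: lengths ~ 0.5..1.5 x mean, so domains are 6..18 bins
    boundaries = []
    pos = 0
    while True:
        length = int(rng.integers(config.mean_tad_bins // 2, config.mean_tad_bins * 3 // 2 + 1))
        pos += max(3, length)
        if pos >= n - 3:
            break
        boundaries.append(pos)
    boundaries = np.array(boundaries, dtype=int)

    # compartment profile: piecewise constant on segments of consecutive TADs
    edges = [0, *boundaries.tolist(), n]
    profile = np.empty(n)
    k = 0
    n_domains = len(edges) - 1
    while k < n_domains:
        g = int(rng.integers(1, 2 * config.mean_segment_tads))
        seg_end = min(k + g, n_domains)
        value = rng.uniform(-1.0, 1.0)
        profile[edges[k] : edges[seg_end]] = value
        k = seg_end

    # loop anchors: half long-range, half short-range, away from the diagonal
    anchors: list[tuple[int, int]] = []
    margin = 12
    tries = 0
    while len(anchors) < config.n_loops and tries < 2000:
        tries += 1
        long_range = len(anchors) < config.n_loops // 2
        if long_range:
            lo, hi = config.long_range_cutoff_bins, n - 2 * margin
        else:
            lo, hi = 25, min(100, n - 2 * margin)
        if hi <= lo:
            lo, hi = 25, n - 2 * margin
        sep = int(rng.integers(lo, hi))
        i = int(rng.integers(margin, n - margin - sep))
        j = i + sep
        if all(abs(i - a) > 4 or abs(j - b) > 4 for a, b in anchors):
            anchors.append((i, j))
    return PlantedTruth(profile, boundaries, anchors)


def _lambda_matrix(
    config: SimConfig,
    profile: np.ndarray,
    boundaries: np.ndarray,
    anchors: Sequence[tuple[int, int]],
    amplitude: float,
    long_range_attenuation: float = 1.0,
) -> np.ndarray:
    """Expected-intensity matrix (unnormalized) for one condition."""
    n = config.n_bins
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx)).astype(float)
    np.fill_diagonal(dist, 1.0)  # no self-distance singularity
    lam = dist ** (-config.decay_exponent)
    lam *= np.exp(amplitude * np.outer(profile, profile))

    # intra-TAD boost
    edges = [0, *np.asarray(boundaries, dtype=int).tolist(), n]
    tad_id = np.empty(n, dtype=int)
    for t in range(len(edges) - 1):
        tad_id[edges[t] : edges[t + 1]] = t
    same_tad = tad_id[:, None] == tad_id[None, :]
    lam[same_tad] *= config.tad_boost

    # loop boost at anchor pairs +-1 bin; long-range anchors attenuated
    for i, j in anchors:
        boost = config.loop_boost
        if j - i >= config.long_range_cutoff_bins:
            boost = 1.0 + long_range_attenuation * (boost - 1.0)
        sl_i = slice(max(0, i - 1), min(n, i + 2))
        sl_j = slice(max(0, j - 1), min(n, j + 2))
        lam[sl_i, sl_j] *= boost
        lam[sl_j, sl_i] *= boost

    # uniform long-range attenuation
    if long_range_attenuation != 1.0:
        far = dist >= config.long_range_cutoff_bins
        lam[far] *= long_range_attenuation
    return lam


def _draw_replicates(
    config: SimConfig, lam: np.ndarray, rng: np.random.Generator
) -> list[ContactMatrix]:
    """Poisson replicate draws sharing lambda; symmetric integer counts."""
    n = config.n_bins
    iu, ju = np.triu_indices(n)
    lam_u = lam[iu, ju]
    lam_u = lam_u * (config.depth / lam_u.sum())
    reps = []
    for _ in range(config.n_replicates):
        c = rng.poisson(lam_u).astype(np.float64)
        counts = np.zeros((n, n))
        counts[iu, ju] = c
        counts = counts + np.triu(counts, 1).T
        reps.append(ContactMatrix("chrS", config.bin_size, counts))
    return reps


def simulate_contact_map(
    config: SimConfig, truth: PlantedTruth | None = None
) -> tuple[list[ContactMatrix], PlantedTruth]:
    """Simulate replicate contact maps under the baseline model.

    Returns one :class:`ContactMatrix` per replicate (identical lambda,
    independent Poisson noise) plus the planted truth.  Identical seeds give
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = _plant_structure(config, rng)
    lam = _lambda_matrix(
        config, truth.true_profile, truth.true_boundaries, truth.loop_anchors,
        config.compartment_amplitude,
    )
    return _draw_replicates(config, lam, rng), truth


def _edit_boundaries(
    boundaries: np.ndarray, deletions: Sequence[int], insertions: Sequence[int]
) -> np.ndarray:
    out = set(int(b) for b in boundaries)
    for d in deletions:
        if int(d) not in out:
            raise ValueError(f"schedule deletes unknown boundary {d}")
        out.discard(int(d))
    out.update(int(i) for i in insertions)
    return np.array(sorted(out), dtype=int)


def simulate_timecourse(
    config: SimConfig, schedule: Sequence[TimepointSpec]
) -> dict[str, tuple[list[ContactMatrix], PlantedTruth]]:
    """Simulate one matrix set per timepoint on a shared bin table.

    All timepoints share the planted baseline structure; each
    :class:`TimepointSpec` perturbs it.  The returned per-timepoint
    :class:`PlantedTruth` records the perturbed profile/boundaries and the
    planted switch labels.
    """
    rng = np.random.default_rng(config.seed)
    base = _plant_structure(config, rng)
    n = config.n_bins
    results: dict[str, tuple[list[ContactMatrix], PlantedTruth]] = {}
    for spec in schedule:
        profile = base.true_profile.copy()
        for region in spec.switch_regions:
            s, e = int(region[0]), int(region[1])
            if not (0 <= s < e <= n):
                raise ValueError(f"schedule references undefined region ({s}, {e})")
            profile[s:e] *= -1.0
        boundaries = _edit_boundaries(
            base.true_boundaries, spec.boundary_deletions, spec.boundary_insertions
        )
        lam = _lambda_matrix(
            config, profile, boundaries, base.loop_anchors,
            config.compartment_amplitude * spec.amplitude_multiplier,
            spec.long_range_attenuation,
        )
        reps = _draw_replicates(config, lam, rng)
        truth = PlantedTruth(
            profile, boundaries, list(base.loop_anchors),
            switch_labels=_switch_labels(schedule),
            perturbation_params={
                "timepoint": spec.name,
                "long_range_attenuation": spec.long_range_attenuation,
                "amplitude_multiplier": spec.amplitude_multiplier,
            },
        )
        results[spec.name] = (reps, truth)
    return results


def _switch_labels(schedule: Sequence[TimepointSpec]) -> dict:
    """Planted switch label per flipped region, from the schedule itself.

    A region is early-affected if its first flip occurs at 1/2/5 min,
    late-affected if at 10/30 min, recoverable iff it is not flipped at
    withdrawal.
    """
    by_tp = {s.name: set(map(tuple, s.switch_regions)) for s in schedule}
    regions = set().union(*by_tp.values()) if by_tp else set()
    labels = {}
    for region in regions:
        flipped_at = [tp for tp in TREATED_TIMEPOINTS if region in by_tp.get(tp, set())]
        if not flipped_at:
            continue
        onset = "early" if flipped_at[0] in EARLY_TIMEPOINTS else "late"
        recovered = region not in by_tp.get("withdrawal", set())
        labels[region] = f"switch,{onset}-affected,{'recoverable' if recovered else 'irrecoverable'}"
    return labels


# ---------------------------------------------------------------------------
# signal tracks


def simulate_signal_track(
    profile: np.ndarray,
    enrichment: float,
    noise_sd: float,
    seed: int = 0,
    chrom: str = "chrS",
    bin_size: int = 40_000,
) -> SignalTrack:
    """Log-normal signal track correlated with a per-bin profile.

    ``signal_i = exp(enrichment * profile_i + eps_i)``, eps ~ N(0, noise_sd).
    """
    profile = np.asarray(profile, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=profile.size) if noise_sd > 0 else 0.0
    values = np.exp(enrichment * profile + eps)
    return SignalTrack(chrom, bin_size, values)


# ---------------------------------------------------------------------------
# point patterns and trajectories


@dataclass
class PointPattern:
    """2-D points with the total observation-window area."""

    points: np.ndarray  # (N, 2)
    area_S: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.area_S <= 0:
            raise ValueError("area_S must be positive")

    @property
    def n(self) -> int:
        return self.points.shape[0]


def simulate_point_pattern(
    kind: str,
    area_side: float,
    n_points: int | None = None,
    parent_rate: float | None = None,
    mean_offspring: float | None = None,
    offspring_scale: float | None = None,
    seed: int = 0,
) -> PointPattern:
    """CSR or Thomas-clustered point pattern in a square window.

    ``kind="csr"``: ``n_points`` uniform points.  ``kind="clustered"``:
    Poisson(parent_rate * area) parents, each with Poisson(mean_offspring)
    offspring displaced by isotropic N(0, offspring_scale^2), reflected back
    into the window.
    """
    if area_side <= 0:
        raise ValueError("area_side must be positive")
    rng = np.random.default_rng(seed)
    if kind == "csr":
        if n_points is None or n_points < 1:
            raise ValueError("csr requires n_points >= 1")
        pts = rng.uniform(0.0, area_side, size=(n_points, 2))
    elif kind == "clustered":
        if None in (parent_rate, mean_offspring, offspring_scale):
            raise ValueError("clustered requires parent_rate, mean_offspring, offspring_scale")
        n_parents = rng.poisson(parent_rate * area_side**2)
        parents = rng.uniform(0.0, area_side, size=(max(n_parents, 1), 2))
        pts = []
        for p in parents:
            k = rng.poisson(mean_offspring)
            if k == 0:
                continue
            off = p + rng.normal(0.0, offspring_scale, size=(k, 2))
            pts.append(off)
        if not pts:
            pts = [parents[:1]]
        pts = np.concatenate(pts, axis=0)
        # reflect strays back into the window
        pts = np.abs(pts)
        pts = area_side - np.abs(area_side - pts)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return PointPattern(pts, area_side**2)


@dataclass
class TrajectorySet:
    """Particle trajectories on a uniform frame interval dt."""

    positions: np.ndarray  # (n_particles, n_frames, 2)
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_particles, n_frames, 2)")
        if self.positions.shape[1] < 2:
            raise ValueError("trajectories need >= 2 frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def simulate_trajectories(
    D: float,
    dt: float,
    n_steps: int,
    n_particles: int,
    loc_error_sd: float = 0.0,
    seed: int = 0,
) -> TrajectorySet:
    """2-D Brownian trajectories: per-axis increments N(0, 2*D*dt), plus
    independent localization noise on every measured position."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    inc = (
        rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_particles, n_steps, 2))
        if D > 0
        else np.zeros((n_particles, n_steps, 2))
    )
    pos = np.concatenate([np.zeros((n_particles, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    if loc_error_sd > 0:
        pos = pos + rng.normal(0.0, loc_error_sd, size=pos.shape)
    return TrajectorySet(pos, dt)
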