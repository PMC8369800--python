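"""End-to-end timecourse analysis driven by a declarative config.

The pipeline simulates (or loads) a multi-chromosome, multi-timepoint Hi-C
experiment and runs every stage in order: depth harmonization, ICE
balancing, O/E, distance decay, compartment analysis (PC1, strength, saddle,
homogeneity, switch classification), TAD analysis (calling, differential
boundaries, reorganization, ATA), significant interactions (calling,
condensate classes, APA), and signal enrichment.  Outputs are plain-text
tables plus a JSON manifest of every threshold, seed, and output file hash;
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from . import decay as decay_mod
from . import enrichment as enr
from . import interactions as inter
from . import tads as tads_mod
from .matrix import (
    ContactMatrix,
    IntervalSet,
    SignalTrack as SignalTrackAlias,
    downsample_to_min,
    ice_balance,
    merge_replicates,
    oe_transform,
    write_bedgraph,
)
from .simulate import (
    TIMEPOINT_ORDER,
    SimConfig,
    TimepointSpec,
    simulate_signal_track,
    simulate_timecourse,
)

log = logging.getLogger("hictempo.pipeline")

__all__ = ["PipelineConfig", "default_schedule", "run_pipeline"]


def default_schedule() -> list[TimepointSpec]:
    """Demo perturbation schedule over the canonical seven timepoints.

    Short-term treatment attenuates long-range contacts and sharpens
    compartmentalization; long-term treatment weakens it; boundaries are
    deleted early and inserted late; two compartment regions switch sign
    (one early-recoverable, one late-irrecoverable).  Region coordinates and
    boundary edits are resolved against the planted structure at run time.
    """
    return [
        TimepointSpec("0"),
        TimepointSpec("1", long_range_attenuation=0.8, amplitude_multiplier=1.2),
        TimepointSpec("2", long_range_attenuation=0.5, amplitude_multiplier=1.5),
        TimepointSpec("5", long_range_attenuation=0.6, amplitude_multiplier=1.3),
        TimepointSpec("10", long_range_attenuation=0.8, amplitude_multiplier=1.0),
        TimepointSpec("30", long_range_attenuation=0.9, amplitude_multiplier=0.7),
        TimepointSpec("withdrawal"),
    ]


@dataclass
class PipelineConfig:
    """Thresholds and shapes of the full timecourse analysis."""

    n_chroms: int = 5
    n_bins: int = 500
    bin_size: int = 40_000
    n_replicates: int = 2
    depth: float = 2_000_000.0
    seed: int = 0
    baseline: str = "0"
    fold: float = 2.0  # strength-change fold
    fdr_tad: float = 0.05
    fdr_int: float = 0.01
    min_oe: float = 10.0
    top_q: float = 0.10
    tad_window: int = 5
    di_span: int = 7
    saddle_n: int = 20
    rcp_distance: float = 10_000_000.0
    apa_k: int = 5
    timepoints: tuple = TIMEPOINT_ORDER

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.baseline not in self.timepoints:
            raise ValueError(f"baseline timepoint {self.baseline!r} missing from timepoints")
        for name, lo, hi in (
            ("fdr_tad", 0, 1), ("fdr_int", 0, 1), ("top_q", 0, 0.5),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} out of range")
        if self.fold <= 1 or self.min_oe < 1:
            raise ValueError("invalid fold/min_oe thresholds")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the manifest dict (also written)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    chrom_seeds = rng_root.spawn(config.n_chroms)

    tps = list(config.timepoints)
    base_tp = config.baseline
    per_chrom: dict[str, dict] = {}

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seed = int(chrom_seeds[ci].generate_state(1)[0] % (2**31 - 1))
        sim_cfg = SimConfig(
            n_bins=config.n_bins, bin_size=config.bin_size, depth=config.depth,
            n_replicates=config.n_replicates, seed=seed,
        )
        # resolve schedule against the planted structure of this chromosome
        schedule = _resolved_schedule(sim_cfg)
        course = simulate_timecourse(sim_cfg, schedule)
        truth0 = course[base_tp][1]

        # stage: depth harmonization across all replicates of all timepoints
        all_reps = [m for tp in tps for m in course[tp][0]]
        all_reps = downsample_to_min(all_reps, seed=seed + 1)
        k = config.n_replicates
        reps_by_tp = {tp: all_reps[i * k : (i + 1) * k] for i, tp in enumerate(tps)}
        log.info("%s: downsampled %d replicate matrices", chrom, len(all_reps))

        # stage: merge + balance + O/E per timepoint
        balanced, oes = {}, {}
        for tp in tps:
            merged = merge_replicates(reps_by_tp[tp])
            merged.chrom = chrom
            bal = ice_balance(merged)
            balanced[tp] = bal
            oes[tp] = oe_transform(bal)
        log.info("%s: balanced %d matrices (%d bins masked at %s)",
                 chrom, len(tps), int(balanced[base_tp].mask.sum()), base_tp)

        orientation = simulate_signal_track(
            truth0.true_profile, enrichment=1.0, noise_sd=0.2, seed=seed + 2,
            chrom=chrom, bin_size=config.bin_size,
        )
        condensate_track = simulate_signal_track(
            truth0.true_profile, enrichment=2.0, noise_sd=0.3, seed=seed + 3,
            chrom=chrom, bin_size=config.bin_size,
        )

        per_chrom[chrom] = {
            "course": course, "truth0": truth0, "balanced": balanced, "oes": oes,
            "reps_by_tp": reps_by_tp, "orientation": orientation,
            "track": condensate_track, "schedule": schedule,
        }

    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }

    # ---- decay ------------------------------------------------------------
    curves = {tp: {} for tp in tps}
    for chrom, d in per_chrom.items():
        for tp in tps:
            curves[tp][chrom] = decay_mod.rcp(d["balanced"][tp])
    rows = []
    for tp in tps:
        if tp == base_tp:
            continue
        fc = decay_mod.rcp_fold_change(curves[tp], curves[base_tp], config.rcp_distance)
        rows.append((tp, fc.mean, fc.sd, fc.p_value))
    df_decay = pd.DataFrame(rows, columns=["timepoint", "mean_log2fc", "sd", "p"])
    _write_tsv(df_decay, outdir / "decay_fold_change.tsv")
    manifest["stages"]["decay"] = {"distance": config.rcp_distance, "n_chroms": config.n_chroms}

    # ---- compartments -----------------------------------------------------
    switch_rows, strength_rows, saddle_rows, homog_rows, pc1_paths = [], [], [], [], []
    for chrom, d in per_chrom.items():
        profiles = {}
        tadsets = {}
        for tp in tps:
            prof = comp.compute_pc1(d["balanced"][tp], d["orientation"], oe=d["oes"][tp], timepoint=tp)
            tset = tads_mod.call_tads(d["balanced"][tp], window=config.tad_window,
                                      p_thresh=config.fdr_tad)
            prof = comp.smooth_by_tads(prof, tset)
            profiles[tp] = prof
            tadsets[tp] = tset
        d["profiles"], d["tadsets"] = profiles, tadsets

        for tp in tps:
            sad = comp.saddle(d["oes"][tp], profiles[tp].pc1, n=config.saddle_n)
            saddle_rows.append((chrom, tp, sad.score))
            try:
                homog = comp.homogeneity(comp.aa_decile_means(d["oes"][tp], profiles[tp]))
            except ValueError:
                homog = float("nan")
            homog_rows.append((chrom, tp, homog))
        st0 = comp.per_bin_strength(d["oes"][base_tp], profiles[base_tp])
        for tp in tps:
            if tp == base_tp:
                continue
            st = comp.per_bin_strength(d["oes"][tp], profiles[tp])
            ch = comp.classify_strength_change(st, st0, fold=config.fold)
            strength_rows.append((chrom, tp, ch["strengthened"], ch["weakened"], ch["unchanged"]))
        sw = comp.classify_switch(profiles)
        for label, value in sw.proportions.items():
            switch_rows.append((chrom, label, value, sw.low_pc1_overlap_p))
        d["switch"] = sw
        track_path = outdir / f"pc1_{chrom}.bedgraph"
        pc1_track = SignalTrackAlias(chrom, config.bin_size, np.nan_to_num(profiles[base_tp].pc1))
        write_bedgraph(pc1_track, track_path)
        pc1_paths.append(track_path)

    _write_tsv(pd.DataFrame(saddle_rows, columns=["chrom", "timepoint", "saddle_score"]),
               outdir / "saddle_scores.tsv")
    _write_tsv(pd.DataFrame(homog_rows, columns=["chrom", "timepoint", "homogeneity_AA"]),
               outdir / "homogeneity.tsv")
    _write_tsv(pd.DataFrame(strength_rows,
                            columns=["chrom", "timepoint", "strengthened", "weakened", "unchanged"]),
               outdir / "strength_change.tsv")
    _write_tsv(pd.DataFrame(switch_rows, columns=["chrom", "label", "proportion", "low_pc1_p"]),
               outdir / "switch_proportions.tsv")
    manifest["stages"]["compartments"] = {
        "saddle_n": config.saddle_n, "fold": config.fold,
        "n_profiles": config.n_chroms * len(tps),
    }

    # ---- TADs -------------------------------------------------------------
    tad_rows, event_rows = [], []
    for chrom, d in per_chrom.items():
        for tp in tps:
            for s, e in d["tadsets"][tp].domains:
                tad_rows.append((chrom, tp, s * config.bin_size, e * config.bin_size))
        di_by_tp = {
            tp: [tads_mod.direction_index(m, span=config.di_span) for m in d["reps_by_tp"][tp]]
            for tp in tps
        }
        ref = d["tadsets"][base_tp]
        for tp in tps:
            if tp == base_tp:
                continue
            changes = tads_mod.test_boundary_change(
                di_by_tp[tp], di_by_tp[base_tp], ref, d["tadsets"][tp],
                fdr=config.fdr_tad, timepoint=tp,
            )
            events, unchanged = tads_mod.classify_reorganization(ref, d["tadsets"][tp], changes)
            for ev in events:
                event_rows.append((chrom, tp, ev.kind, ";".join(map(str, ev.boundaries))))
        oe0 = d["oes"][base_tp]
        ata_mat, intra = tads_mod.ata(oe0, ref)
        d["ata_intra"] = intra
    _write_tsv(pd.DataFrame(tad_rows, columns=["chrom", "timepoint", "start", "end"]),
               outdir / "tads.tsv")
    _write_tsv(pd.DataFrame(event_rows, columns=["chrom", "timepoint", "type", "boundaries"]),
               outdir / "tad_events.tsv")
    manifest["stages"]["tads"] = {"window": config.tad_window, "span": config.di_span,
                                  "fdr": config.fdr_tad, "n_events": len(event_rows)}

    # ---- interactions -----------------------------------------------------
    call_rows, apa_rows = [], []
    for chrom, d in per_chrom.items():
        merged0 = merge_replicates(d["reps_by_tp"][base_tp])
        merged0.chrom = chrom
        table = inter.aggregate_tad_pairs(merged0, d["tadsets"][base_tp])
        calls, _ = inter.call_significant(table, fdr_thresh=config.fdr_int, min_oe=config.min_oe)
        chrom_tag = sum(chrom.encode())  # stable across processes
        seed_cls = int(
            np.random.SeedSequence([config.seed, chrom_tag]).generate_state(1)[0] % (2**31 - 1)
        )
        try:
            calls = inter.classify_by_signal(calls, d["track"], top_q=config.top_q, seed=seed_cls)
        except ValueError:
            pass
        for c in calls:
            call_rows.append((chrom, c.anchor_a[0], c.anchor_a[1], c.anchor_b[0], c.anchor_b[1],
                              c.observed, round(c.oe, 4), c.fdr, c.klass, c.distance))
        # APA of planted long-range loop anchors across timepoints
        anchors = [p for p in d["truth0"].loop_anchors
                   if (p[1] - p[0]) >= SimConfig().long_range_cutoff_bins]
        for tp in tps:
            try:
                res = inter.apa(d["oes"][tp], anchors, resolution=config.bin_size, k=config.apa_k)
                apa_rows.append((chrom, tp, res.center_score, res.corner_score(), res.n_aggregated))
            except ValueError:
                apa_rows.append((chrom, tp, float("nan"), float("nan"), 0))
    _write_tsv(pd.DataFrame(call_rows, columns=["chrom", "a_start", "a_end", "b_start", "b_end",
                                                "observed", "oe", "fdr", "class", "distance"]),
               outdir / "interaction_calls.tsv")
    _write_tsv(pd.DataFrame(apa_rows, columns=["chrom", "timepoint", "center_score",
                                               "corner_score", "n_pairs"]),
               outdir / "apa_scores.tsv")
    manifest["stages"]["interactions"] = {"fdr": config.fdr_int, "min_oe": config.min_oe,
                                          "top_q": config.top_q, "n_calls": len(call_rows)}

    # ---- enrichment -------------------------------------------------------
    enr_rows = []
    for chrom, d in per_chrom.items():
        prof = d["profiles"][base_tp]
        high = prof.pc1 > 0.8
        if high.any():
            regions = _bins_to_intervals(high, chrom, config.bin_size)
            track = d["track"]
            track.chrom = chrom
            fe = enr.fold_enrichment(track, regions)
            rho = enr.pseudo_cluster_correlation(track, regions)
            p = enr.region_vs_rest_test(track, regions)
            enr_rows.append((chrom, "high_pc1_A", fe, rho, p, int(high.sum())))
    _write_tsv(pd.DataFrame(enr_rows, columns=["chrom", "region_set", "fold_enrichment",
                                               "spearman_rho", "ranksum_p", "n_bins"]),
               outdir / "enrichment.tsv")
    manifest["stages"]["enrichment"] = {"n_region_sets": len(enr_rows)}

    # ---- manifest ---------------------------------------------------------
    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bedgraph")):
        manifest["outputs"][path.name] = _sha256(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _resolved_schedule(sim_cfg: SimConfig) -> list[TimepointSpec]:
    """Bind the demo schedule's boundary edits and switch regions to the
    planted structure of this chromosome (deterministic in the seed)."""
    from .simulate import _plant_structure

    rng = np.random.default_rng(sim_cfg.seed)
    truth = _plant_structure(sim_cfg, rng)
    b = truth.true_boundaries
    delete = (int(b[len(b) // 3]),) if b.size >= 3 else ()
    mids = [(s + e) // 2 for s, e in truth.domains(sim_cfg.n_bins)]
    insert = (int(mids[len(mids) // 2]),) if len(mids) >= 2 else ()

    # two planted switch regions aligned to profile segments
    segs = _profile_segments(truth.true_profile)
    segs = [s for s in segs if (s[1] - s[0]) >= 5 and abs(s[2]) > 0.2]
    early = tuple(segs[0][:2]) if segs else ()
    late = tuple(segs[-1][:2]) if len(segs) > 1 else ()

    base = default_schedule()
    out = []
    for spec in base:
        sw = []
        if early and spec.name in ("2", "5", "10", "30"):
            sw.append(early)
        if late and spec.name in ("30", "withdrawal"):
            sw.append(late)
        out.append(
            TimepointSpec(
                spec.name, spec.long_range_attenuation, spec.amplitude_multiplier,
                boundary_deletions=delete if spec.name in ("2", "5") else (),
                boundary_insertions=insert if spec.name in ("30",) else (),
                switch_regions=tuple(sw),
            )
        )
    return out


def _profile_segments(profile: np.ndarray) -> list[tuple[int, int, float]]:
    segs = []
    start = 0
    for i in range(1, profile.size + 1):
        if i == profile.size or profile[i] != profile[start]:
            segs.append((start, i, float(profile[start])))
            start = i
    return segs


def _bins_to_intervals(member: np.ndarray, chrom: str, bin_size: int) -> IntervalSet:
    recs = []
    start = None
    for i, m in enumerate(member.tolist() + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            recs.append((chrom, start * bin_size, i * bin_size, "region"))
            start = None
    return IntervalSet(pd.DataFrame(recs, columns=["chrom", "start", "end", "name"]))
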