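# hictempo

Time-resolved Hi-C analysis of chromatin reorganization during
biomolecular-condensate disruption.

Brief treatment of cells with 1,6-hexanediol dissolves liquid-like nuclear
condensates within minutes, and Hi-C maps taken along such a timecourse show
the genome reorganizing at every scale: long-range contacts weaken, A/B
compartmentalization sharpens and then relaxes, intra-A interactions
homogenize, intermediate compartments switch identity, TADs fuse, shift and
separate, and condensate-associated long-range interactions lose strength.
`hictempo` implements the complete analysis stack for this kind of
experiment — and a planted-truth simulator so every stage can be verified
quantitatively without any sequencing data.

## What it computes

For each chromosome and timepoint, starting from binned cis contact
matrices (sparse triplet text + BED bin table):

- **Normalization** — random subsampling of all replicates to the smallest
  library, ICE (iterative correction) balancing to equal bin visibility,
  and the observed/expected transform O/E(i,j) = m(i,j) / d(|i−j|), where
  d(k) is the mean balanced contact at bin separation k.
- **Distance decay** — relative contact probability (RCP) in log-spaced
  distance strata, normalized to sum to 1; per-chromosome
  log2(RCP_t/RCP_0) fold changes with a paired t test; fractions of bin
  pairs above/below the untreated replicate mean at a fixed distance.
- **Compartments** — PC1 as the leading eigenvector of the Pearson
  correlation matrix of the O/E map, oriented by a gene-density-like track
  (A = positive); TAD-level smoothing; per-bin compartment strength
  (mean same-type O/E ÷ mean cross-type O/E); saddle plots over PC1
  quantiles with a corner-contrast score; mean interactions between PC1
  ranges; homogeneity of A-A interactions as 1/CV², i.e. mean²/variance of
  PC1-decile group means; run-length compartment regions; and a timecourse
  switch classifier with early/late-affected × recoverable/irrecoverable
  subtypes plus a hypergeometric test of switch-region overlap with
  low-PC1 (−0.5 < PC1 < 0.5) bins.
- **TADs** — diamond bin-signal domain calling (window 5 at 40 kb) with a
  rank-sum boundary filter; replicate-aware differential boundaries from
  direction indices (span 7) via a tag-count-weighted t statistic with BH
  correction (FDR < 0.05); fusion/shifting/separation event classification;
  aggregate TAD analysis (ATA) of resized O/E domains.
- **Significant interactions** — contacts aggregated over TAD pairs; an
  upper-tail hypergeometric p-value per distal pair given its marginal
  totals and the grand total, BH-corrected (FDR < 0.01), with an O/E ≥ 10
  filter against the distance-decay background; classification of calls as
  condensate-enriched / absent / random by anchor overlap with top-decile /
  bottom-decile / randomly sampled signal bins; per-class distance
  distributions with rank-sum tests; aggregate peak analysis (APA) windows.
- **Enrichment** — fold enrichment (median in-region signal ÷ genome-wide
  median), Spearman correlation with a ±1 pseudo-cluster track, Wilcoxon
  rank-sum region-vs-rest tests, and peak-density profiles around classed
  boundaries.
- **Imaging statistics** — Ripley's
  K(r) = (S/(N−1))·(1/N)·ΣᵢΣ_{j≠i} 𝟙[r_ij ≤ r] and L(r) = √(K/π) for
  point patterns, and MSD with overlapping time origins,
  msd₃D = 1.5 × msd₂D, with a diffusion coefficient from the initial slope
  (D = slope/4).

The simulator (`hictempo.simulate`) plants all of this ground truth:
power-law decay s^−α, compartment structure exp(c·eᵢ·eⱼ) on a
piecewise-constant eigenprofile, TAD blocks, loop anchors, Poisson
replicates, and per-timepoint perturbations (long-range attenuation,
amplitude scaling, boundary edits, compartment sign flips).

## Worked example

```python
import numpy as np
from hictempo import SimConfig, simulate_contact_map, simulate_signal_track
from hictempo.matrix import ice_balance, merge_replicates, oe_transform
from hictempo.compartments import compute_pc1, saddle
from hictempo.tads import call_tads, boundary_f1

cfg = SimConfig(n_bins=500, seed=7)          # 20 Mb chromosome at 40 kb
reps, truth = simulate_contact_map(cfg)      # 2 replicates + planted truth
bal = ice_balance(merge_replicates(reps))
oe = oe_transform(bal)

track = simulate_signal_track(truth.true_profile, 1.0, 0.2, seed=99)
prof = compute_pc1(bal, track, oe=oe)
valid = ~np.isnan(prof.pc1)
print("PC1 vs truth r =", round(np.corrcoef(prof.pc1[valid],
                                            truth.true_profile[valid])[0, 1], 3))
print("saddle corner score =", round(saddle(oe, prof.pc1, n=20).score, 2))
tads = call_tads(bal)
print("boundary F1 =", round(boundary_f1(tads.boundaries,
                                         truth.true_boundaries), 3))
```

prints

```
PC1 vs truth r = 0.983
saddle corner score = 2.96
boundary F1 = 0.987
```

i.e. the compartment eigenvector tracks the planted profile almost
perfectly, same-type contacts are ~3× enriched over cross-type in the
saddle corners, and ~99% of planted TAD boundaries are recovered within one
bin.

The full timecourse pipeline runs from the shell:

```bash
hictempo pipeline run --outdir out/ --seed 1
```

writing per-stage TSV/BED/bedGraph tables and a `manifest.json` of every
threshold and output hash (byte-identical across runs at a fixed seed).
Per-stage subcommands (`simulate`, `balance`, `oe`, `rcp`, `pc1`,
`call-tads`, `enrich`, `ripley`, `msd`, ...) operate on the same text
formats.

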