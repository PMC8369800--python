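# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hictempo`. All coordinates are 0-based half-open (BED);
bin `i` covers `[i·bin_size, (i+1)·bin_size)`. All contact-map statistics
are cis, computed per chromosome.

## Generative model of the simulator

`simulate_contact_map` draws symmetric integer count matrices from a
Poisson model with intensity

    λ_ij ∝ |i−j|^−α · exp(c·e_i·e_j) · t^[i,j in same TAD] · l^[(i,j) near an anchor]

- **Distance decay** `α` (default 1.0): the contact-probability exponent of
  mammalian interphase chromatin at the megabase scale.
- **Compartment profile** `e_i`: piecewise constant with values
  Uniform(−1, 1). Segments are unions of consecutive planted TADs (mean
  ~25 bins at ~12-bin TADs), so the profile is exactly constant within
  every TAD. This encodes the biological premise that a TAD lies in a
  single compartment — the same premise that justifies TAD-level PC1
  smoothing — and provides both strong and intermediate compartment
  regions for the PC1-range analyses.
- **Compartment amplitude** `c` (default 1.0): dimensionless checkerboard
  contrast. The multiplicative `exp(c·e_i·e_j)` form makes same-sign pairs
  enriched and opposite-sign pairs depleted symmetrically on the log scale.
- **TAD boost** `t` (default 3) and **loop boost** `l` (default 3): the
  boost applies to all intra-domain pairs, and to 3×3 windows centred on
  each planted anchor pair. Half the planted anchors are long-range
  (≥ the long-range cutoff, default 250 bins = 10 Mb at 40 kb), half
  short-range.
- **Depth** (default 2×10⁶ expected pairs per replicate for a 500-bin
  chromosome) with two replicates differing only by Poisson noise. Counts
  are integer draws so that downsampling and the hypergeometric test see
  realistic discreteness. λ_ii uses distance 1 — the main diagonal is
  excluded downstream, so no self-distance convention can leak into
  results.

`simulate_timecourse` applies per-timepoint perturbations over the
canonical schedule {0, 1, 2, 5, 10, 30, withdrawal} minutes:

- **Long-range attenuation** `f`: multiplies λ uniformly at separations
  beyond the cutoff *and* shrinks the loop excess of long-range anchors to
  `1 + f·(l−1)`. The uniform part drives the RCP fold-change signal; the
  loop part is what APA can see, because O/E renormalizes every distance
  stratum to mean 1 and is therefore blind to a purely uniform long-range
  scale factor. Both are one biological statement — long-range contacts,
  including the enriched ones, weaken.
- **Amplitude multiplier**: scales `c`; values > 1 sharpen
  compartmentalization (saddle corners rise, per-bin strength grows),
  values < 1 homogenize it (PC1-decile group means converge, 1/CV² rises).
- **Boundary deletions/insertions** edit the planted TAD partition.
- **Switch regions** flip the sign of `e_i` on stated intervals; the
  schedule records for each region whether its first flip is early
  (1/2/5 min) or late (10/30 min) and whether it reverts at withdrawal.

Effect sizes in the demo schedule (attenuation 0.5 at 2 min, sharpening
×1.5, late weakening ×0.7) were chosen once for detectability at desk-scale
depth; they are directions-only claims in the source experiment and carry
no quantitative meaning beyond that.

What the simulator does **not** emulate: trans contacts, copy-number and
mappability artifacts, fragment-level biases (GC, restriction-site
density), distance-dependent noise beyond Poisson, and polymer physics of
condensates. Passing tests therefore demonstrate the correctness of the
estimators under a clean generative model, not robustness to every
real-data artifact.

## Normalization

- **Downsampling**: multivariate-hypergeometric thinning of the
  upper-triangle counts to the smallest total — sampling valid pairs
  without replacement, which preserves expected cell proportions exactly.
- **ICE**: univariate row-sum iterative correction,
  `b_i ← b_i·s_i/mean(s)`, stopping when `max_i |s_i/mean(s) − 1| < 1e−6`
  (cap 200 iterations). Bins with zero coverage, or row sum below the 0.02
  quantile of nonzero row sums, are masked first (the source pipelines do
  not state their low-coverage filter; this approximates the usual
  behavior of ICE implementations). Weights are rescaled so the balanced
  matrix keeps the raw total, which leaves every downstream ratio
  statistic unchanged.
- **O/E**: per-distance mean of the balanced matrix over non-masked pairs;
  by construction the mean O/E of every populated stratum is exactly 1
  (to float precision), which the tests assert at 1e−9.

## Compartments

PC1 is the leading eigenvector of the Pearson correlation matrix of the
O/E map (masked and constant bins removed), sign-oriented against a
gene-density-like track and rescaled so the 99th percentile of |PC1| is 1.
The rescaling gives fixed thresholds (0.4 / 0.5 / 0.8) a stable meaning on
synthetic data, where the raw eigenvector scale is arbitrary. The leading
eigenvalue's share of the spectrum is reported as a confidence indicator;
near-zero planted amplitude yields a visibly smaller share.

Per-bin strength uses O/E values (not balanced counts): mean same-type
O/E over mean cross-type O/E per bin. Strength-change classes are
symmetric: strengthened at ratio ≥ 2, weakened at ≤ 0.5.

The saddle uses 50 PC1-quantile groups by default (20 on short synthetic
chromosomes so each group keeps ≥ 15 bins), with PC1 trimmed to the
(0.005, 0.995) quantile range first; the corner score is the mean of the
AA and BB corner blocks (extreme 20% of quantiles) over the mean of the
AB corners. Under a null (O/E ≡ 1) the score is exactly 1.

Homogeneity is mean²/sample-variance (1/CV², ddof = 1) of group-mean
interactions. The groups are the within-A PC1-decile pair means — "average
interactions between all A-type loci" grouped at decile granularity, which
matches the granularity at which homogenization is visible. The statistic
is scale-invariant and returns +inf on zero variance.

The switch classifier works on per-bin label trajectories over the seven
timepoints; bins filtered at any timepoint are excluded, maximal runs of
identical trajectories form regions, and a region is a switch when any
treated timepoint's label differs from 0 min. Onset is early if the first
change is at 1/2/5 min, late at 10/30 min; recoverable iff the withdrawal
label equals the 0-min label. Switch-region overlap with low-PC1 bins
(−0.5 < PC1 < 0.5 at 0 min) gets an upper-tail hypergeometric p-value.

## TADs

The bin signal at gap `i` is the mean balanced contact in the diamond
`{(u, d): i−w < u ≤ i < d ≤ i+w}` (w = 5 at 40 kb), truncated at ends.
Candidate boundaries are local minima within ±w; each candidate is tested
by a one-sided rank-sum comparison of its diamond values against pooled
interior diamonds of the two flanking provisional domains, and candidates
are kept at BH-adjusted p < 0.05. The BH step is deliberate: local-minimum
selection biases candidate p-values low, so a raw threshold admits several
spurious boundaries per null chromosome, while BH reduces that to near
zero without hurting recovery of genuine boundaries (F1 ≥ 0.9 at boost 3).

Differential boundaries: per replicate, direction indices up_i / down_i
are raw contact sums over span 7 up/downstream; the log directionality
ratio log((down+0.5)/(up+0.5)) is compared between conditions with a
two-sample t statistic whose replicate contributions are weighted by tag
count (up+down+1), BH across candidate boundaries, FDR < 0.05. This is a
deliberately simple, contract-faithful replacement for a quasi-likelihood
GLM: with two replicates per condition the GLM's dispersion estimation is
barely identified anyway, and the weighted t statistic controls the null
false-change rate at nominal level in simulation.

Event classification: lost boundaries pair with gained boundaries within
2 bins (nearest first, ties to the left) as shifts; unpaired losses merge
two reference domains (fusion); unpaired gains split one (separation).
Every significant change lands in exactly one event.

ATA resizes each domain window (flanks of 0.5× the domain length per
side) to a fixed pixel grid by bilinear interpolation and averages across
domains, NaN-aware.

## Significant interactions

Raw contacts are aggregated over TAD pairs. For each distal pair the
p-value is the upper tail of a central hypergeometric distribution with
the pair's marginal totals and the grand total — the no-enrichment limit
of the noncentral model — BH-corrected at FDR < 0.01. The O/E filter
(≥ 10) uses an expected count from the distance-decay background
aggregated at TAD-pair level; the background uses the per-distance
*median* raw count (mean fallback at sparse distances) so that a single
strongly boosted pair cannot inflate its own expectation. The two parts
are complementary: the marginal-based hypergeometric is conservative at
long range and liberal near the diagonal, while the decay-based O/E is
distance-exact, and a call must clear both.

Condensate classes: a call is *enriched* when both anchors intersect a
top-decile signal bin, *absent* for bottom-decile, *random* for a
seed-recorded uniform 10% bin sample, with precedence
enriched > absent > random; quantile ties break by bin index. A constant
track is rejected as non-informative.

APA averages (2k+1)² O/E windows at anchor pairs, filtering pairs within
k bins of the matrix edge or diagonal; the center score is the central
3×3 mean (< 3 bins, i.e. < 120 kb at 40 kb resolution) and the corner
score the mean of the four 3×3 corner blocks.

## Imaging statistics

Ripley's K is the plain density-normalized estimator with no edge
correction — the estimator is taken exactly as stated, and the vectorized
implementation is tested for exact equality against an O(N²) double loop.
The cost of no edge correction is a negative bias near the window border:
on a unit square the estimator's expectation is
`S·(πr² − (8/3)r³ + r⁴/2)` rather than πr², a −3% bias at r = 0.05·side.
CSR calibration tests therefore compare the Monte-Carlo mean against this
closed-form expectation (4-SEM envelope) at radii ≤ 5% of the window side,
where the deviation from πr² stays below 10%. Units of S and of the point
coordinates must simply be consistent; the code is unit-agnostic.

MSD uses overlapping time origins (all valid start frames), maximizing
data use at the cost of correlated lag estimates — acceptable because the
diffusion fit uses only the first 4 lags, where the correlation is mild.
The 3D estimate is 1.5× the 2D curve (isotropy assumption). `fit_diffusion`
fits slope and intercept, so static localization error moves the intercept
only.

## Pipeline

`run_pipeline` executes downsample → balance → O/E → decay → compartments
→ TADs → interactions → enrichment per chromosome over the seven-timepoint
schedule, with per-chromosome seeds spawned from the root seed
(`numpy.random.SeedSequence`). The demo configuration is 5 chromosomes ×
500 bins × 2 replicates × 7 timepoints at 2×10⁶ pairs per replicate — a
problem size chosen so the whole demo runs in well under a minute per
chromosome while every planted effect stays detectable. The manifest
records config, thresholds, per-stage summaries, and a SHA-256 hash of
every output file; no timestamps enter any output, so identical
config + seed gives byte-identical manifests.

## Known limitations

- The distance→resolution mapping for changed-interaction quantification
  follows the published table, which lists "1 Mb" for two different
  resolutions; this package maps 100 Mb→500 kb, 10 Mb→100 kb, 1 Mb→40 kb,
  100 kb→25 kb and documents the apparent typo at the first entry.
- PC1 is eigenvector-based; likelihood-based compartment callers can
  produce differently scaled profiles, shifting membership of fixed
  PC1-range thresholds.
- The hypergeometric interaction test ignores distance within its p-value;
  calibration near the diagonal relies on the O/E filter.
- Ripley's K without edge correction under-counts near borders; restrict
  radii or supply pre-cropped interior windows for unbiased estimates.
- The simulator's replicates share λ exactly; biological replicate
  variability beyond counting noise is not modeled, so differential tests
  see an easier null than real data would pose.
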