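# Methods

This note documents the models, conventions and numerical choices behind the
pipeline, and what the synthetic-data generator does and does not emulate.

## Morphology representation and subregions

A reconstruction is a rooted tree of 3D sample points with radii (SWC
semantics); coordinates are micrometres and are taken as already co-registered
— no transform is applied on read. Reading validates ids, single-rootedness,
parent references and connectivity; zero-length edges are permitted but
flagged. Writing re-indexes nodes 1..N, parents before children. Group and
registration-parameter labels come from a manifest CSV
(`path,group,sample_id,regparam_id`), not from SWC content.

Subregions follow the anatomy of the neuron: the root of the analyzed tree is
the first bifurcation of the primary neurite; the **main branch** (MB) is the
two daughter paths up to and including their first bifurcations, the
**dorsal** and **ventral branches** (DB/VB) are the subtrees distal to those
bifurcations, and the **whole arborization** (WA) is their union. Junction
nodes are shared between MB and DB/VB, but every edge belongs to exactly one
subregion, so cable is conserved under the split (asserted to 1e-9 relative
in the tests). A daughter path with no bifurcation leaves its branch empty
(with a warning), matching reconstructions whose main branch is a single
unbranched stretch. A soma/primary-neurite tree is carried if supplied but
excluded from analysis.

## Scalar morphometrics

Nineteen measures are computed per subregion. Six are the headline group
discriminators: width (x extent), height (y extent), total dendritic volume
(conical frusta, `π·h/3·(r₁² + r₁r₂ + r₂²)` per edge), maximum centrifugal
order (bifurcations on the root path), average partition asymmetry
(`|l−r|/(l+r−2)` over bifurcation tip counts) and the Hausdorff (box-counting)
fractal dimension. The complement is a canonical set: depth (z extent),
bifurcation/tip/node counts, frustum lateral surface, maximum root→tip path
length, maximum root→node Euclidean distance, mean branch order, mean
segment length, mean radius, maximum branch length, tip-count-weighted tree
asymmetry and mean branch contraction (chord/path).

Conventions:

* **Multifurcations** are decomposed into (n−1) binary splits in child order;
  tip counts are conserved.
* **The subregion root's own split is excluded** from partition-asymmetry
  measures: it is the cropped primary-neurite bifurcation, not a dendritic
  branch point. This makes the asymmetry of an unbranched main branch
  *missing* (N/A) rather than a spurious 0.
* **Missing values** (no bifurcations, degenerate geometry) propagate as NaN;
  a group summary involving any missing sample is reported N/A.
* **Medians** for even n are the mean of the two central order statistics;
  the change in median is `100·(median_F − median_NE)/median_NE`.
* Mann–Whitney tests are two-sided at a per-measure 5% cutoff with no
  multiplicity correction across measures (as in the original analysis).

### Box-counting fractal dimension

Edges are resampled at 1 μm; the point cloud is rotated to its principal
axes with canonical (third-moment-positive) signs, making the estimate
invariant to rigid rotation of the reconstruction by construction. Occupied
boxes N(s) are counted over the ladder s = diag/2^j (j = 1..7), each count
taken as the minimal cover over five diagonal grid offsets, with per-axis
index clamping into ⌈extent/s⌉ boxes so a bare line of length L occupies
~L/s boxes without alignment inflation. The slope of log N vs log(1/s) is
fit over the scaling window N(s) ≥ 16 and s ≥ 2 μm — coarse scales are
excluded because their counts carry mostly bounding-box edge effects, which
bias the slope downward. Degenerate geometry (diagonal < 10 resampling
steps) or a window with fewer than two scales yields NaN. On a straight
200 μm segment the estimate is 0.97; on a dense planar grid 1.8–1.95.

## Shell and voxel density

PDL_shell / PDL_voxel are the percentages of a morphology's dendritic length
inside concentric 20 μm spherical shells (around a configurable center,
default: the WA root of the first NE reference morphology) and inside
non-overlapping 20 μm half-open cubic voxels (grid origin (0,0,0) of the
registered frame; boundary points belong to the higher-index voxel). Both
clippings are *analytic*: each straight edge is intersected exactly with the
sphere radii (quadratic roots) or the axis-aligned grid planes (vectorized
breakpoint accumulation), so per-morphology bin values sum to exactly 100 and
agree with a 0.01 μm resampling oracle to < 0.1 percentage points per bin.

### Factorial testing

Each bin is tested with an aligned-rank-transform (ART) two-way ANOVA with
factors maturation (NE/F) × registration-parameter set: per effect, the raw
response is aligned by subtracting the other effects' estimates (cell and
least-squares marginal means) and the grand mean, midranked, and submitted to
a classical two-way fixed-effects ANOVA on the ranks (Type-III-style model
comparison on effect-coded designs, so unbalanced cells are handled); only
the aligned-for effect's p is read. A bin is flagged iff the maturation main
effect is significant at α/m (Bonferroni, m = bins actually tested) *and* the
interaction is not significant at α = 0.05, i.e. the difference must be
independent of registration parameters.

**Inclusion rule**: only bins with nonzero PDL in at least half the
morphologies of *each* group are tested — bins essentially absent in one
group lack factorial coverage. This rule is a stated convention (the original
analysis does not document its rule). MB is excluded from the shell analysis
(it is a short unbranched stretch).

## Proximal/distal partitioning

Every node carries `%PL = 100·PL_root/(PL_root + PL_term_max)` (path length
to the root over that plus the maximum path length to a downstream
terminal): 0 at the root, 100 at terminals, invariant under uniform spatial
scaling. Node %PL values are pooled per voxel across groups, registration
sets and samples; a voxel is *distal* when the pooled median exceeds 90.

Partition-level tests use one response per morphology: its total PDL share
over the partition's tested voxels. Pooling individual voxel values as
records would treat thousands of highly dependent numbers as independent
observations; summing per morphology makes the ANOVA error term honest
between-reconstruction variation at the study's actual design size
(2 groups × 6 samples × 9 registration sets). Bonferroni is applied across
the partitions tested (m = 2). The *reported* change in median PDL_voxel per
partition is still computed from the pooled voxel values, mirroring how the
distributions are usually displayed. The per-voxel flags use the pooled
per-voxel records as described above.

## Electrophysiology

Activity periods relative to a stimulus spanning [onset, offset]:
spontaneous [onset−3 s, onset), on-phasic [onset, onset+75 ms), inhibitory
[onset+75 ms, offset), rebound [offset+25 ms, offset+100 ms). Period rates
are spike counts in the half-open window divided by its duration, averaged
over trials; one feature row per neuron. Relative Inhibition is
`1 − rate_inhibitory/rate_spontaneous` (undefined for silent spontaneous
activity). T0 is the first spike latency, defined only when it falls inside
the on-phasic window; T1–T3 are the subsequent interspike intervals,
NaN when spikes are missing.

**Spike detection** (for voltage input; the source study does not document
its extraction): 3rd-order Butterworth high-pass at 100 Hz (zero-phase),
upward crossings of median + 5 SD of the filtered trace, ≥ 2 ms apart,
localized at the raw-trace maximum within the refractory span. All three
parameters are configurable; on the synthetic templated traces detection
recovers ground-truth spikes to < 0.5 ms.

**Rate profiles**: spike times pooled over trials are smoothed with Gaussian
kernels. The global bandwidth minimizes the cross-validation cost
`C(w) = Σ_ij k_{√2w}(Δ_ij) − 2 Σ_{i≠j} k_w(Δ_ij)` over a log-spaced grid
(pairwise terms computed on an evenly spaced subsample of at most 1200 spikes
— the optimum is stable under subsampling); local bandwidths then adapt as
`w_i = w·√(G/pilot(t_i))` (pilot = fixed-bandwidth density interpolated from
a grid, G its geometric mean). With fewer than 20 pooled spikes a fixed
Scott's-rule bandwidth is used. Edge mass is conserved by reflecting
near-boundary spikes at the span limits, so the profile integral equals the
mean spike count per trial (verified to < 2%). The confidence band is a
percentile bootstrap over trials (seeded).

Group comparisons report group means, percent change of means, Mann–Whitney
p per feature, Welch's unequal-variance t for Relative Inhibition, and
per-group OLS slopes of inhibitory vs spontaneous rate.

## Synthetic data

The generator's purpose is *recovery of known parameters*, not biological
realism; its defaults mirror the study conditions (6 vs 6 samples, 9
registration-parameter sets, 1 s stimulus at 265 Hz, 20.833 kHz sampling).

**Morphologies.** Because the study compares co-registered reconstructions of
the *same identified neuron* across animals, one archetype tree is grown per
population (stochastic binary outgrowth from a root with two labeled
daughter trunks; segments ~8 μm; radial-zone-dependent branching; short
terminal twigs decorating all zones) and each sample is a structural variant
of it: rare terminal-twig dropout plus a small affine deformation and node
jitter. Per-sample structural variation is deliberately kept at or below the
per-registration-set rigid jitter so that within-cell ANOVA errors are
effectively independent and the imposed group effect is the only systematic
between-group difference — with large per-sample structural variation the
repeated-measures design (the same six animals appear in every
registration-set cell) would amplify chance 6-vs-6 asymmetries into spurious
significance, in the synthetic data and in real data alike.

The group effect is applied once at the archetype level (the forager neuron
consistently lacks the same material): a proximal factor f < 1 removes many
short terminal twigs spread across the radial zone r < r_split (120 μm by
default) whose hosts are path-proximal (%PL < 85) and whose entire cable
lies in the proximal *core* — voxels whose %PL median stays well below the
partition threshold (≤ 75), probed densely along each removed edge. The
restriction matters: material in voxels whose class can flip under jitter,
or whole subtrees whose removal zeroes a few remote voxels, would smear the
effect into the distal partition. Any remaining shortfall is recovered by
gently smoothing core through-paths (each interior node moves toward its
neighbors' midpoint, bounded to ~1 μm per step, confined to its own voxel,
with the moved edges re-probed against the core), which removes tortuosity
cable diffusely and in place. Total arbor cable is conserved by default
through compensatory outgrowth: a single gently curving process extends from
the outermost terminal radially outward, leaving the arbor's envelope within
one segment — mirroring a redistribution of dendritic length (proximal
reduction, distal outgrowth) rather than net shrinkage, and ensuring
percent-normalized densities in pre-existing voxels are not mechanically
inflated elsewhere. The per-tree zone cable before/after the effect is
recorded as ground truth; over many seeds the mean proximal cable ratio of
F to NE reproduces the requested factor to within ~3%.

What the morphology generator does **not** emulate: real between-animal
shape variability (samples are near-clones of the archetype), registration
failure modes, reconstruction artifacts (gaps, diameter noise), or realistic
neuropil-shaped arbor anisotropy. Passing tests therefore show the
*machinery* attributes a known density redistribution to the correct
partition under the study's factorial design — not that the pipeline is
robust to arbitrary morphological noise.

**Spike trains** are piecewise-constant-rate renewal processes over the four
periods with a 2 ms dead time; within each constant-rate segment intervals
are `refractory + Exp(λ*)` with the hazard `λ* = λ/(1 − λ·refractory)`, so
the realized rate equals the nominal rate, and each segment starts in
equilibrium (the first event is drawn from the forward-recurrence
distribution), so even the short 75 ms windows carry no start-up bias (mean
counts verified to 3 SE at 1000 trials). Optional voltage synthesis places a biphasic ~2.5 ms
action-potential template at each spike over Gaussian noise at the study
sampling rate. The paper-like presets (NE: spontaneous 13, on-phasic 100,
inhibitory 7, rebound 30 Hz; F scaled to ≈ +40% spontaneous and ≈ +95%
rebound) are conventions for end-to-end rehearsal, not measured values;
per-neuron lognormal rate heterogeneity (CV 0.12 by default) provides
between-neuron variance.

## Test and acceptance problem sizes

The acceptance suite runs the clipping oracle on 50 generated trees at
0.01 μm resampling, exact Mann–Whitney enumeration for all sample sizes up
to 6×6, 1000 null and 200 power simulations for the ART calibration at the
2×6×9 design, 100 seeded population runs for the partition-effect recovery,
and 1000-trial spike-rate recovery — sizes chosen to give stable Monte-Carlo
estimates while keeping a full run in the minutes range on one CPU.

## Known limitations

* The deposited recordings are not bundled; the reproduction tests against
  the published group changes require the user to export them (see README).
* The shell/voxel inclusion rule and the per-morphology partition response
  are stated conventions where the original analysis is not documented.
* The 19-measure registry beyond the six headline measures is a canonical
  complement, not a verified replica of the original measure list.
* ART ANOVA alignment uses cell/least-squares marginal means; other ART
  variants differ in unbalanced designs.
* The NIX/Spike2 trial format is not read directly; trials enter as
  spike-time CSV (or voltage arrays through the detection function).
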