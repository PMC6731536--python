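# dlint1

Analysis pipeline for maturation-related changes in DL-Int-1, an identified
vibration-sensitive interneuron of the honeybee (*Apis mellifera*) primary
mechanosensory center. The package compares morphological reconstructions and
stimulus-locked intracellular recordings between two maturation groups —
newly emerged adults (NE, 1–3 days) and foragers (F, >10 days) — and ships a
synthetic-data module with known ground truth so the whole pipeline can be
exercised and validated without the original recordings.

## What it computes

**Morphology arm** (SWC reconstructions, co-registered to a common frame,
split into whole arborization WA, main branch MB, dorsal branch DB, ventral
branch VB):

1. *Scalar morphometrics* — 19 metric and topological measures per subregion
   (extents, frustum volume/surface, branch/tip counts, maximum centrifugal
   order, partition asymmetry, box-counting fractal dimension, …), compared
   between groups with two-sided Mann–Whitney *U* tests and summarized as
   min/median/max per group with the change in median
   `100·(median_F − median_NE)/median_NE`.
2. *Radial (Sholl-style) density* — the percentage of dendritic length in
   concentric 20 μm spherical shells (PDL_shell), per shell tested with
   aligned-rank-transform (ART) two-way ANOVA over maturation × registration
   parameter set, Bonferroni-corrected across shells; a shell is flagged only
   if the maturation effect is significant *and* the interaction with the
   registration nuisance factor is not.
3. *Voxel density and proximal/distal partitions* — the percentage of
   dendritic length in non-overlapping 20 μm voxels (PDL_voxel), the
   normalized group change per voxel
   `ΔPDL_voxel^norm = (mean_F − mean_NE)/mean_all`, and a partition of space
   into proximal/distal by path-length remoteness
   `%PL = 100·PL_root/(PL_root + PL_term_max)` (distal ⇔ pooled median
   %PL > 90), with ART factorial tests per voxel and per partition.

**Electrophysiology arm** (trial-segmented spike times around a 1 s, 265 Hz
vibration stimulus): firing rates in four activity periods — spontaneous
(3 s before onset), on-phasic (first 75 ms), inhibitory (until offset),
rebound (75 ms starting 25 ms after offset) — plus
`Relative Inhibition = 1 − rate_inhibitory/rate_spontaneous`, the on-phasic
spike-timing features T0–T3 (first-spike latency and first three interspike
intervals), adaptive-kernel firing-rate profiles with bootstrap bands, and
group comparisons (Mann–Whitney, Welch's *t* for Relative Inhibition, OLS
slopes of inhibitory vs spontaneous rate).

## Worked example

Generate a synthetic study (6 NE vs 6 F morphologies × 9 registration
parameter sets, with a 10% proximal-only density reduction imposed on the
forager group) and run the morphology arm:

```bash
dlint1 synth-morph --out demo/morph --seed 1 --proximal-factor 0.9
dlint1 morph --manifest demo/morph/manifest.csv --out demo/report --seed 1
```

`demo/report/partition_summary.csv` then contains (seed 1):

```
subregion,partition,n_voxels,ne_median,f_median,change_in_median_pct,p_maturation,p_regparam,p_interaction,flag
WA,proximal,925,0.0610,0.0575,-5.73,1.0e-21,0.997,0.89,True
WA,distal,687,0.0347,0.0348,+0.29,0.61,0.20,0.73,False
...
```

i.e. the maturation effect on voxel density is detected in the proximal
partition (p ≈ 1e-21, no interaction with registration parameters) and not in
the distal one — recovering the generator's ground truth. The ephys arm works
the same way from a spike-time CSV:

```bash
dlint1 synth-ephys --out demo/spikes.csv --seed 1
dlint1 ephys --spikes demo/spikes.csv --out demo/report
```

`demo/report/ephys_group_comparison.csv` reports, among others, a spontaneous
rate change of +39.7% (Mann–Whitney p = 0.002) and a rebound change of
+102.3% for the paper-like presets (designed changes +40% / +95%).

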