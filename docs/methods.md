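# Methods

This note records the model, the processing rules, the defaults, and the
design decisions behind `wavegrn`, including the places where a choice was
genuinely open and what was chosen.

## The enhancer-switching circuit

Each cell carries three genes. Gene *i*'s transcription rate is a weighted
sum of its two enhancers' activities, minus first-order decay with rate λ:

    dG_i/dt = α_i D_i + β_i S_i − λ G_i

The **dynamic enhancers** wire a repressilator-like clock — each is
repressed by the next gene in the cycle (1→2→3→1) and multiplied by the
speed-regulator concentration R ∈ [0, 1]:

    D_i = R / (1 + G_{succ(i)}^n)

The **static enhancers** wire a multi-stable network — each requires
self-activation, is repressed by the other two genes, and is multiplied by
the inverse gradient:

    S_i = (1−R) · G_i^n/(1+G_i^n) · Π_{j≠i} 1/(1+G_j^n)

Reporter genes transcribe at one enhancer's rate and decay at λ
(`dRD/dt = D_g − λ·RD`, likewise for RS; the reporters read gene 2 by
default). The decay term is implemented as −λ·G(t): λ is a first-order mRNA
decay rate, so decay must be proportional to the current level.

**Algebraic vs relaxation regulation.** D and S are implemented as
instantaneous algebraic functions of the current gene state. Treating them
as ODE states without decay would integrate without bound, so the only
self-consistent ODE reading is a first-order lag; that mode is available
(`ds_mode="relaxation"`, time constant `relaxation_tau`) for sensitivity
analysis, and as τ → 0 its oscillation period converges to the algebraic
mode's (tested). The two modes are never mixed in a comparison. Euler
integration in relaxation mode requires dt < τ (stability guard).

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| n | 5 | strong, saturating regulation; the printed simulation value |
| λ | 0.5 /time | printed simulation value |
| α | (1.5, 1.5, 1.5) | printed simulation value |
| β | (1, 1, 1) strong / (0.5, 0.5, 0.5) weak | the two printed regimes |
| cells | 100 | one cell ≈ one nucleus column across the germband |
| gradient | linear, 0 (anterior) → 1 (posterior) | simplest shape satisfying "gradient in space" with max 1; exponential and custom shapes, and linear-in-time posterior retraction, are options |
| ICs | G = (1, 0, 0) per cell, reporters 0 | the symmetric all-zero state is a fixed point of the clock and never ignites; seeding one gene breaks the symmetry identically in every cell |
| integrator | euler, dt = 0.01, t_max = 60 | ≈ 8 clock cycles at R = 1; euler at dt=0.01 differs from rk4 by < 1e-3 (tested), and positivity is automatic for dt·λ < 1 |

With β = 0.5 the static network has no stable on-state (β·G^n/(1+G^n) = λG
has no positive solution for β ≤ λ·2·G* in this regime), so stripes decay
after formation; with β = 1 the on-state at G ≈ 1.93 is stable and stripes
persist. This is the entire difference between the two regimes.

**Deletion experiments** zero one gene's α (dynamic) or β (static). With
α₂ = 0 and G₂(0) = 0, G₂ stays exactly 0: the static enhancer needs
self-activation, so the gene can never ignite. With β₂ = 0 the posterior
keeps oscillating but no anterior stripe of G₂ forms; the anterior instead
carries the homogeneous dynamic-driven baseline G₂ ≈ α·R/λ (≈ 0.27 at the
R = 0.1 boundary), a smooth ramp joining the posterior domain. An
"anterior stripe" is therefore defined as an above-threshold run (threshold
10% of the intact run's maximum) **fully contained** in the anterior zone
(R < 0.1): a localized band. A raw per-cell level test would misread the
baseline ramp at the zone boundary as expression even though no band exists.

**No noise, no coupling.** The equations contain neither; cells interact
only through the shared gradient. A seed exists solely for optional
initial-condition jitter.

## Wave analysis

AP convention, package-wide: index 0 = anterior, posterior to the right.

- **Kymographs** are (time × position). From a simulation the kymograph is
  the raw (time × cell) slice. From tracked nuclei, intensities are binned
  by AP position per frame (mean by default); empty bins are NaN and stay
  NaN in stored data — they are linearly interpolated only transiently for
  peak detection.
- **Wave tracks** link per-frame peaks (scipy `find_peaks` with a
  prominence floor) greedily across consecutive frames: candidate pairs
  within `max_link_distance` accepted by increasing distance, ties broken
  by lower position. In the operating regime (frame-to-frame peak motion
  below half the peak spacing) greedy linking coincides with the optimal
  bipartite assignment (tested against the Hungarian algorithm); in
  adversarial configurations they can differ, which is why an optimal mode
  exists for nucleus tracking (below).
- **Classification**: least-squares slope of peak amplitude vs position.
  Negative slope (gains toward the anterior) → static-like; positive →
  dynamic-like; |slope| below threshold → ambiguous. The threshold defaults
  to 5% of the track's amplitude range per full axis length — chosen to
  absorb numerical ripple, stated explicitly because no numeric criterion
  exists upstream, where the trend was read from intensity-distribution
  plots. Long-lived *stationary* peaks are stabilized stripes, not waves;
  wave statistics therefore require a net drift of > 5% of the axis.

## MS2 movie processing

Stages and the decisions inside them:

1. **Max z-projection** per frame.
2. **CLAHE** (tile size 128 px; output normalized to [0, 1]); a constant
   image passes through unchanged, an oversized tile falls back to a single
   tile with a warning.
3. **Nucleus segmentation**: the projected image is Gaussian-smoothed
   (σ = 3 px, so pixel noise cannot split or drop maxima), local maxima
   with intensity ≥ half the image maximum seed a watershed on the inverted
   intensity, restricted to pixels above 10% of max. Centroids are
   intensity-weighted.
4. **Spot detection**: 3D DoG (σ = 1.2/2.4 voxels by default), candidate
   maxima pruned by an h-maxima transform with height `tolerance` — the
   ImageJ-style "stand out above the saddle" rule; a dimmer punctum within
   `tolerance` of its saddle to a brighter neighbor merges into it — then a
   lower `threshold` on the DoG value. Maxima on the volume border are
   dropped (truncated nuclei pile up edge maxima). Spot intensity is the
   raw-volume sum over a 3×3×3 neighborhood (the estimator itself is a
   package choice; nothing upstream defines one). The default σ, tolerance
   2.5 and threshold 5.0 were calibrated once on the synthetic fixture —
   the knobs are exactly the ones described as "set empirically" — and are
   in raw-intensity units of that fixture; real movies need their own
   values via config.
5. **Assignment**: label under the spot's (y, x); background spots go to
   the nearest centroid within `max_radius` (default 12 px), else stay
   unassigned. One punctum per nucleus: the brightest wins, others are
   flagged.
6. **Tracking**: greedy nearest-centroid linking within `max_displacement`
   (default 8 px/frame); unmatched old nuclei terminate tracks, unmatched
   new ones start tracks. Optimal (Hungarian) matching behind
   `optimal=True`. The upstream description names only an external strategy,
   so greedy linking is this package's stated choice.
7. **mRNA estimation**: centered moving average, window 10 frames, edges
   truncated to the available frames (window parity: offsets −4..+5).
   Whether the original average was centered or trailing is unknowable from
   the description; centered introduces no lag, which matters when
   correlating against ground-truth activity. Frames with no assigned spot
   contribute 0 — transcription off — matching the accumulated-activity
   reading of the smoothed signal.

## Synthetic data: what it emulates, what it does not

**Movies** (default 320 × 160 px, 20 z-planes, 50 frames, 50 nuclei —
about a minute of compute per movie): nuclei are 3D Gaussian blobs
(σ = 7 px lateral, 5 z; peak 25 over background 10) on a jittered grid,
advected by an affine drift (0.25 px/frame AP) plus a per-nucleus random
walk (σ = 0.15 px/frame) — the slow nuclear flow of germband movies, not a
fitted flow field. A nucleus transcribes while its activity (a parametric
traveling pulse, or a simulated species trajectory) exceeds 0.1; its single
punctum (σ = 1.2 voxels) then has peak `snr·σ_bg·(0.5 + 0.5·activity)`:
transcription sites are bursty on/off objects, so an "on" site never fades
to nothing, and the SNR knob is the full-activity punctum peak over the
total background noise σ (2% read noise plus Poisson shot noise). Ground
truth (positions, activities, spot locations) is returned alongside and
everything is bit-reproducible from the seed.

Not emulated: optics (no PSF anisotropy or depth attenuation by default),
photobleaching, nuclear divisions, z-motion, spot sub-voxel shape. Passing
the benchmark therefore shows the chain is correct and robust to
shot/read noise and slow flow — not that the default thresholds transfer to
any particular microscope.

**Accessibility matrices**: log-normal baselines (log-mean 3, log-sd 1),
design 3 regions × 2 time points × 3 replicates, replicate noise log-sd
0.3 (`dispersion`). Differential sites (default 25%) are assigned
round-robin to `n_clusters` distinct up-group patterns shifted by
`effect_size` (default 1.5 natural-log units ≈ 4.5-fold) in the flagged
groups. This emulates the *structure* of a differential-accessibility
result — it does not emulate count statistics, TMM normalization or the
FDR machinery, which sit upstream of this package's scope; differential
flags here are ground-truth labels, not test outcomes.

**Peak sets / coverage tracks**: true regions with uniform boundary jitter
and dropout (spacing validated so jitter can never merge neighbors);
constant-background tracks with spiked bins. These exist to make the
consensus and blacklist rules falsifiable against known truth.

## Accessibility rules

- Consensus merging: transitive ≥ 1 bp overlap, union span, kept with
  calls from ≥ 2 distinct samples. Verified against a brute-force
  union-find oracle.
- Blacklist: mean across libraries per 50 bp bin ≥ 100 (inclusive),
  adjacent flagged bins merged.
- Most-variable sites: row mean > median of row means AND row SD > Q3 of
  row SDs. Quantiles by linear interpolation between order statistics
  (numpy default, R type 7 — the convention of the upstream environment);
  SDs are sample SDs (ddof = 1). Under a null matrix the joint rule selects
  well under 30% of sites (mean and SD of log-normal rows are positively
  correlated, so the joint tail exceeds the independent 12.5% but stays
  below 25%).
- Clustering: per-site z-scoring, k-means with `restarts` random
  initializations (default 1000, mirroring an nstart-style best-of rule),
  best inertia kept, deterministic given the seed. Zero-variance sites are
  an error naming the row.
- Construct-site overlap: |intersection| ≥ 0.9 × |site| — asymmetric by
  construction. Association counts a construct as differential-overlapping
  if ≥ 1 differential site passes the rule ("any differential site"; the
  treatment of mixed overlaps was open and this choice is flagged in the
  output). Constructs overlapping no site at all are counted
  non-differential and listed. Whether the overlap rule should run against
  consensus sites or per-sample peaks was also open; consensus sites are
  assumed. Percentages are rounded to one decimal.

## Numerical and degenerate-input choices

- Euler positivity: update is a convex combination for dt·λ < 1 (enforced);
  rk4 intermediate states are clamped at 0 (undershoot is O(dt⁵)).
- Non-finite states raise an error naming the first offending step and cell.
- Peak-linking and tracking tie-breaks are deterministic (distance, then
  lower index).
- Degenerate wave tracks (all records at one position) classify ambiguous
  with direction stationary.
- Empty/zero images yield empty label maps and no spots rather than errors.

## Problem sizes

The test suite and the reproduction script run the default 100-cell
simulations (6000 steps), two 50-frame/50-nucleus movies at SNR 5, a
600-site clustering matrix with 50 k-means restarts, and oracle checks on
~1000 random intervals — sizes chosen so the full suite completes on one
CPU in a few minutes while leaving every pipeline stage with enough data to
fail visibly if wrong.

## Known limitations

- The model is 1D, deterministic and uncoupled; it cannot address stripe
  splitting, noise-induced desynchronization, or tissue deformation.
- Greedy tracking has no gap closing: a single missed detection splits a
  track (the synthetic benchmark shows the segmentation is stable enough
  that this does not occur at default settings; real movies may differ).
- The spot-detection defaults are fixture-calibrated intensity values, not
  transferable constants.
- The association analysis takes activity and differential flags as given;
  it quantifies co-occurrence, not causation, and with 11 constructs the
  Fisher exact test is underpowered (p ≈ 0.55 on the encoded panel).
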