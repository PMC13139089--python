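# Methods

## Scope and data model

`norkit` post-processes markerless pose estimates; it does not train or run
a pose network. Input is the DeepLabCut CSV dialect (three header rows —
scorer, bodyparts, coords — then per-frame `x, y, likelihood` triplets) for
the five-landmark mouse schema *nose tip, left ear, right ear, body centre,
tail base*, in pixels. The file carries no time base, so the frame rate is
config-supplied (default 30 fps, the usual industrial-camera setting for
this paradigm). Calibration is a single scalar `px_per_cm`, e.g. the arena
width in pixels divided by its known width (50 cm default arena); the
coordinate convention (image axes, y down) is irrelevant downstream because
all geometry uses distances and angles only. HDF5 pose files, multi-animal
tracking and 3-D pose are out of scope.

The experiment configuration is declarative (YAML/JSON) and fails closed:
unknown keys are errors, because a silently ignored typo in a threshold
name would change the science without a trace. Exactly two objects with
distinct roles (novel/familiar) are required, and their zones at the
largest threshold must be disjoint (centre distance > r₁ + r₂ + 2·2 cm),
which in turn guarantees that exploration masks for the two objects are
mutually exclusive frame by frame.

## Track cleaning

1. **Confidence gate** — frame-landmarks with likelihood below
   `likelihood_cutoff` (default 0.6, common practice for DLC output) become
   missing.
2. **Gap fill** — interior missing runs up to `max_interp_gap_s` (default
   0.5 s) are linearly interpolated per coordinate; at 30 fps and sub-cm
   inter-frame motion nothing fancier is justified. Longer occlusions (a
   mouse behind an object can lose the nose marker for seconds) are *not*
   guessed: those frames stay invalid for all event logic, and
   leading/trailing gaps are never extrapolated.
3. **Calibration** to cm.

Per-landmark counters (`n_dropped`, `n_interpolated`) ride on the track and
surface in the CLI log and run manifest, so the effect of these choices is
auditable per session. An optional running-median smoother (odd window,
default off) exists but is deliberately not part of the default chain:
smoothing biases threshold crossings at bout edges. The chain is idempotent.

## Event definition

Distance is measured to the object's **footprint boundary** (circular
footprint, radius ≥ 0), not its centre — "2 cm from the object" then means
the same thing for a small and a large object. The graded nose thresholds
are 1, 1.5 and 2 cm; body-centre and combined modes are fixed at 2 cm; the
touch mode uses a 0.2 cm contact margin (one tracking-jitter scale above
literal contact).

The **head-triangle orientation gate** computes the head direction as the
unit vector from the ear midpoint to the nose. A frame passes only if this
vector lies within `orientation_half_angle_deg` (default 45°; the gate can
be ablated by setting 180°) of the nose-to-object-centre direction. Two
degenerate cases: if the nose sits inside the footprint the gate passes
unconditionally (the target direction is ill-conditioned at contact), and
if the nose is within 0.05 cm of the ear midpoint the head direction is
undefined and the frame is invalid for all orientation-gated modes.

Qualifying-frame runs are debounced: runs separated by ≤ `merge_gap_s`
(default 0.2 s) of non-qualifying frames merge, and merged runs shorter
than `min_bout_s` (default 0.1 s) are discarded — sub-100 ms threshold
crossings at 30 fps are tracking jitter, not sniffing. Both default to
configurable values and can be set to 0 to recover a raw per-frame
definition. Frequency is the number of surviving bouts; duration is their
summed length. Note that bout *counts* are not monotone in the threshold
(merging can join bouts at a wider threshold); only mask-time is, which is
what the nesting invariants assert. Climbing is not excluded by default; an
`exclude_climbing` switch (body centre inside the footprint invalidates
nose-mode frames) is available.

The vectorized segmenter is verified against an independent frame-by-frame
enumerator (`brute_force_events`) on thousands of random masks.

## Indicator registry and preference

36 indicators: 6 modes × {frequency, duration} × {novel, familiar} = 24,
plus frequency- and duration-preference per mode = 12. Names encode mode,
threshold and role (`NT1.5_dur_familiar`, `NTBC2_dur_pref`, …). The
*traditional* family is the six NT(2) indicators — what a human rater
scores — and the *refined* family the remaining thirty. The preference
formula is the single most consequential convention in the registry and is
configurable: the default is the novelty share `novel/(novel+familiar)` ∈
[0, 1]; the discrimination index `(novel−familiar)/(novel+familiar)` ∈
[−1, 1] is the alternative. When an animal explored neither object in a
mode the preference is **missing**, never 0 — a 0 would be a strong
familiar-preference claim. Object roles come from the configuration, not
from behavior; NOR vs OLR needs no computational distinction (a paradigm
tag is carried for reporting only).

## Group statistics

Per indicator: Shapiro–Wilk on each group (α = 0.05); if either rejects,
Mann–Whitney U (asymptotic, tie-corrected); otherwise classic mean-centred
Levene, choosing Student's t (homogeneous) or Welch's t. Effect sizes:
pooled-SD Cohen's d on both t paths, with the first (reference) group
first, so an increase in the comparison group yields negative d; rank
r = |Z|/√(n₁+n₂) from the tie-corrected normal approximation (without
continuity correction, the standard convention for this effect size — the
p-value itself uses the continuity-corrected asymptotic method).
Benjamini–Hochberg correction is applied within each family (6 traditional,
30 refined tests). Degenerate inputs: a zero-variance sample is treated as
failing normality (Shapiro–Wilk is undefined on it); two identical constant
groups return p = 1, effect 0 by convention; indicators with fewer than 3
defined values per group (e.g. a preference undefined for most animals) are
reported as untestable rather than aborting the family. Subjects dropped
for missing values are counted and reported.

Manual-vs-system concordance is Pearson r (association) plus a paired
t-test on the differences (systematic bias), per indicator over paired
subjects.

Calibration is verified by simulation: under three null shapes (normal
equal-variance, normal with 3× SD ratio, exponential; n = 7 per group,
1000 replicates) the workflow's rejection rate at α = 0.05 stays within
the 99% binomial band, and its power at a 2σ shift matches the closed-form
noncentral-t power within 3 points.

## Synthetic sessions and ground truth

The generator emulates a 10-minute test-phase session at 30 fps in a
50 × 50 cm arena. The body centre performs a reflecting correlated random
walk (speed 6 cm/s, per-frame heading diffusion SD 0.4 rad, 3 cm wall
margin) that is pushed out of a 5 cm exclusion band around each object
between bouts, so background motion produces no accidental exploration. The
head is rigid — nose 2 cm ahead of the body centre, ears ±1 cm at 1.2 cm
behind the nose — so the ear-triangle orientation gate is exercised on
every frame; rigid kinematics were chosen over independent landmark walks
for exactly this reason. A scripted bout parks the nose at a commanded
distance from the object footprint facing the object (or rotated 120° off
target for deliberately non-oriented bouts). Noise is applied last:
Gaussian jitter (σ = 0.1 cm, a plausible tracking-error scale well below
the 0.5 cm threshold spacing) and 5% likelihood dropouts at likelihood 0.1.
Same seed, same bytes.

Ground truth is recomputed from the realized noise-free trajectory — not
the script — with plain vectorized geometry, so detector tests compare
against the identical geometry rather than intentions. Group studies derive
one seed per subject from a master seed; subjects vary in bout count
(4–8 per object), bout duration (0.8–2.0 s), nose distance (0.2–1.6 cm,
30% touch bouts), and the injected effect multiplies novel-object bout
durations in the comparison group.

What the generator does *not* emulate: realistic gait and body deformation,
gradual approach/withdrawal trajectories (bouts are step changes), rearing
and climbing postures, heavy-tailed tracking outliers, and identity swaps.
Passing tests therefore demonstrate correctness of the scoring pipeline on
known geometry, not pose-estimator accuracy on real video — validating the
latter still requires a manual-concordance study on real recordings, which
the `validate` workflow supports.

## Problem sizes and numerical choices

The test suite and acceptance script use full-scale single sessions
(10 min × 30 fps = 18 000 frames), 100 sessions for nesting invariants,
1000 replicates per null-calibration scenario, and 50 (tests) / 20
(acceptance script) replicate studies of 2 × 7 subjects for
effect-detection — sizes at which every asserted statistic is stable.
Threshold comparisons use ≤ with a 1e-12 cosine tolerance at the
orientation boundary; bout-duration comparisons carry a 1e-9 guard so
exact-length bouts at `min_bout_s` are kept. Metric CSVs are written with
`%.17g`-style full precision and read back with round-trip float parsing,
so tables survive write/read cycles bit-for-bit.
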