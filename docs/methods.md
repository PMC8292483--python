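# Methods

This note records the quantitative definitions the package implements,
the defaults and why, what the synthetic generators emulate, and the
numerical choices made where the underlying procedures are commonly
left unspecified in the literature.

## Kinematics

Tracking tables hold predator centroid, a head point, and prey centroid
at a uniform frame rate (50 frames/s default). Derived series:

* **Speed** — path length of the predator centroid per 200-ms bin
  divided by the bin duration, with the step joining two bins
  attributed to the earlier bin so uniform motion at `v` gives exactly
  `v` per complete bin. Path length (not endpoint displacement) is
  used so within-bin turns are not undercounted; the choice matters
  only for strongly curved paths at this bin width. Missing frames are
  linearly interpolated up to 3 frames; longer gaps make the affected
  bins missing (never zero).
* **Azimuth** — signed angle from the centroid→head vector to the
  centroid→prey vector, `atan2`-based, in (−180°, 180°] with the
  anti-collinear tie reported as +180°. Frames with a degenerate head
  vector are missing.
* **PPD** — Euclidean centroid→prey distance.

Speed is translation/rotation invariant, azimuth rotation-equivariant,
and PPD isometry-invariant; the test suite asserts all three.

## Approach-episode segmentation

An episode must satisfy two criteria: the predator–prey distance
decreases until it drops below 3 cm, and the azimuth stays within
±90°. "Decreases" is formalized with a running-minimum rule: within an
episode no PPD sample may exceed the running minimum (since episode
start) by more than `jitter_tol = 0.5` cm. This tolerates tracking
jitter while bounding cumulative creep — a literal monotonicity
requirement shatters episodes at any realistic noise level.

The segmentation is deterministic and scan-based:

1. **End candidates** are first crossings below 3 cm (previous frame
   ≥ 3 cm) at which the azimuth criterion holds.
2. Each candidate is **extended backward** as far as both criteria
   allow (running-minimum rule, azimuth in range, PPD present), never
   crossing an earlier episode.
3. The **start** is placed at the last frame attaining the extension's
   PPD maximum — the latest local maximum preceding the descent.
4. Episodes separated by less than `min_gap = 0.5` s merge, but only
   when every bridging frame keeps the azimuth criterion (otherwise
   the merged interior would violate it).
5. Episodes shorter than `min_duration = 0.2` s (one speed bin) are
   discarded; peak speed needs at least one bin.

An independent brute-force implementation (exhaustive interval
re-checking) lives in the test suite; the two are held exactly equal on
randomized series.

Per-episode peak speed is the maximum binned speed among frames inside
the episode. Undefined metrics (no attacks, no episodes) are explicit
`None` — zero is a valid frequency and is never used as a missing
marker. Per-mouse averages skip undefined trials and report how many
trials defined each metric.

## Single-unit analyses

* **Antidromic identification** — per pulse, the first spike within a
  10-ms search window gives a latency. Identified iff median latency
  < 5 ms, response reliability ≥ 0.5, and Pearson r between the mean
  pulse-evoked and mean locomotion-evoked waveforms ≥ 0.9. The
  latency criterion is standard; the reliability and similarity
  cutoffs are package defaults (the qualitative requirement is
  "faithful following with a comparable waveform") and are exposed as
  parameters.
* **Peri-event alignment** — 20-ms PSTH bins over a ±2-s window;
  Z-score against the mean/SD of the trial-averaged rate in the
  [−2, −1] s baseline window (chosen to sit well before the ~100-ms
  response leads under study). A zero baseline SD flags the response
  as degenerate rather than producing infinities.
* **Onset/offset** — threshold at baseline + 0.15 × (peak − baseline);
  onset is the first upward crossing before the peak that holds for 3
  bins, offset the first sustained return after the peak, both with
  sub-bin linear interpolation. No smoothing is applied by default,
  so piecewise-linear responses reproduce the analytic crossing
  exactly; spike PSTHs should pass `smooth_sigma = 0.05` (50-ms
  Gaussian), which the package's own spike analyses and examples do.
  Smoothing biases sharp onsets early by up to ~σ, which is why it is
  opt-in rather than default.
* **Speed tuning** — locomotion bouts (hysteresis 3/1 cm/s, ≥ 1 s) are
  cut into non-overlapping 500-ms windows; each contributes (mean
  speed, spike count / 0.5 s). Windows are binned into nine 3-cm/s
  speed bins over 3–30 cm/s; per-unit curves are min–max normalized.
  Spearman's ρ is computed at the bin level by default (window level
  available), with an exact enumeration p-value for n ≤ 8 and the t
  approximation above. Because bins hold unequal window counts, the
  package also provides a window-level permutation test for the binned
  statistic (`speed_tuning_permutation_p`): permuting bin ranks is
  anti-conservative under heteroscedastic bin means, while permuting
  the window→speed pairing and re-binning is exactly valid.

## Photometry

ΔF/F uses a running 10th-percentile baseline over 30 s by default
(tracks slow bleaching, ignores transients; a global percentile is
selectable). ΔF/F is exactly invariant to positive gain on the raw
trace. Event-triggered averages reuse the shared onset estimator;
negative onsets mean the fluorescence leads the event.

Evoked amplitude = max of the pulse-averaged ΔF/F within 1 s
post-pulse minus the 1-s pre-pulse mean. The estimator is exactly
unbiased on noiseless input; optional boxcar smoothing exists for noisy
single-pulse data but attenuates sharp transient peaks (~15% at 0.1 s),
so it is off by default. The input–output curve is the mean amplitude
per laser power (control channel reported alongside); antagonist
suppression is the treated/control ratio of mean amplitudes.

## Gait and looming escape

Stance onsets: paw velocity in the body frame, projected on the travel
direction, smoothed (5-frame moving average), Schmitt-triggered at
±25% of its robust amplitude with a 100-ms refractory interval; the
onset time is refined to sub-frame precision by intersecting lines fit
to the swing and stance sides of the body-frame position apex (exact on
noiseless piecewise-linear traces, which makes zero-noise recovery of
planted gait parameters exact). Step frequency = (n−1)/(last−first
onset); stride = mean ground-frame paw displacement between consecutive
onsets. At 50 frames/s the default smoothing resolves stepping up to
~6 Hz; faster gaits need `smooth_frames=1` and a shorter refractory
interval (the swing phase shrinks below 3 frames).

Escape metrics use declared windows: before = 10 s pre first stimulus,
during = first onset → last onset + 2 s, after = 10 s post
during-window. These extents are package defaults, not values recovered
from any publication.

## Puncta

Between-class-variance (Otsu) thresholding by default, fixed threshold
selectable. Puncta are 8-connected components with pixel area within
[min, max] gates (defaults reject single-pixel noise; touching puncta
merge and count once). Density = count / mask area in µm²; normalized
density = target density / reference density, which cancels pixel size
and staining/imaging gain. An area-fraction mode exists for labeling
too dense to resolve into components.

## Synthetic data: what it emulates, and what a green test establishes

Generators fan a single integer seed into independent per-stream
generators; identical seeds give bit-identical outputs, and every
planted quantity is recorded in a JSON-serializable `GroundTruth`.

* **Hunting trials** — a behavioral script alternating gaps (prey on a
  bounded random walk, predator retreating with head pointed away from
  prey, so exactly the azimuth criterion is violated), pure-pursuit
  approaches at a constant per-episode speed of 20–30 cm/s against
  prey fleeing at 4 cm/s (PPD strictly decreasing), and sub-3-cm
  contact dwells during which jaw attacks are a Poisson process
  (1 /s), with the final attack forced at the capture time. Trials
  plant 10–20 episodes by default. Gaussian position noise (default 0;
  0.1 cm in recovery tests) is added to all tracked points. The
  constant-speed approach makes the planted peak speed equal the
  binned-speed peak exactly at zero noise. Not emulated: curved
  pursuit paths, prey evasion strategies, occlusions, identity swaps —
  so green recovery tests establish correctness of the criteria
  implementation, not robustness to all tracking pathologies.
* **Spike trains** — inhomogeneous Poisson with rate = baseline +
  slope × speed(t + lead) (defaults 5 Hz, 0.8 Hz per cm/s, 100-ms
  lead), clipped at zero; treadmill speed alternates rests (3–5 s)
  with bouts (2–4 s, peaks 10–30 cm/s, 0.25-s linear ramps — the ramp
  makes the 15%-onset estimate land at the planted lead for a 20-cm/s
  bout, since the 3-cm/s bout threshold is 15% of 20). A light-pulse
  block follows the behavior; evoked spikes occur at the planted
  latency ± jitter with 95% reliability, waveforms are a biphasic
  template + noise. Bursting, adaptation, and drift are not modeled.
* **Photometry** — transients are impulses convolved with a unit-peak
  dual-exponential kernel (20-ms rise, 500-ms decay), amplitude 0.05
  ΔF/F (locomotion) or a saturating power map × suppression factor
  (evoked), on F₀ = 100 a.u. with 0.5% Gaussian noise. Evoked pulses
  are spaced 4 s (≥ 8 decay constants) so transients never overlap —
  at 2-s spacing residual decay contaminates the pre-pulse baseline by
  several percent. Bleaching and motion artifacts are not modeled.
* **Gait** — ideal trot (diagonal pairs in antiphase), duty cycle 0.6,
  body at 20 cm/s with 4-Hz stepping (stride 5 cm) by default.
* **Looming** — constant-speed exploration (8 cm/s) with smooth
  turning, a 40-cm/s dash 100 ms after the first of three stimulus
  onsets (1 s apart), then freezing; because binned speed is path
  length per bin, planted speeds are recovered exactly at zero noise.
* **Puncta** — non-overlapping bright disks (radius 3 px, separation ≥
  one diameter + 2 px) on a noisy background inside the region mask.

## Known limitations

* The episode detector's start rule (latest PPD maximum before the
  descent) is one of several defensible conventions; alternatives
  shift episode onsets by up to the pre-descent plateau length.
* The bin-level Spearman ρ of a tuning curve depends on bin occupancy;
  the window-level permutation test is the calibrated inference path.
* Gait analysis assumes straight-line walking (travel direction from
  net body displacement); runway data fits this, open-field data does
  not.
* Puncta counting undercounts when puncta touch (merged components);
  the area-fraction mode is the fallback for dense labeling.
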