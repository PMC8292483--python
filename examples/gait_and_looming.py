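"""Runway gait quantification and looming-escape metrics.

Gait: paw traces of a mouse walking at 20 cm/s with 4-Hz stepping are
analyzed for per-paw step frequency and stride length (stride = body
speed / step frequency = 5 cm).  Looming: locomotion speed around three
overhead looming stimuli is summarized by the peak escape speed during
the stimuli and the average speeds before (exploration) and after
(freezing).
"""

import pursuitkit as pk
from pursuitkit.simulate import (
    GaitParams,
    LoomingParams,
    generate_gait,
    generate_looming_trial,
    session_from_trial,
)

paws, truth = generate_gait(GaitParams(paw_noise_sd=0.1, seed=1), 10.0)
steps = pk.detect_steps(paws)
gait = pk.gait_summary(steps, paws)
print(f"planted: {truth.step_frequency} Hz steps, {truth.stride_length} cm stride")
for paw in ("LF", "RF", "LH", "RH"):
    print(
        f"  {paw}: {len(steps[paw])} steps, "
        f"{gait.step_frequency[paw]:.2f} Hz, stride {gait.stride_length[paw]:.2f} cm"
    )
print(f"fore-paw aggregate: {gait.fore_step_frequency:.2f} Hz, {gait.fore_stride_length:.2f} cm")

traj, stim, ltruth = generate_looming_trial(LoomingParams(seed=2))
session = session_from_trial(traj, stim)  # 200-ms speed bins
esc = pk.escape_metrics(session)
print(
    f"looming escape: peak during stimuli {esc.peak_speed_during:.1f} cm/s "
    f"(planted {ltruth.escape_speed}), before {esc.avg_speed_before:.1f} cm/s "
    f"(planted {ltruth.baseline_speed}), after {esc.avg_speed_after:.1f} cm/s (freezing)"
)
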