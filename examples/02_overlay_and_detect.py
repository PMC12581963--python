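"""Superimpose pacing artefacts on a VF episode and run the ICD detector.

Shows the central interaction mechanism: a large pacing spike restarts the
auto-adjusting sensitivity threshold high, masking the smaller VF deflections.
"""

from pacesense import (
    OverlaySpec,
    VfModelParams,
    generate_vf_episode,
    loop_episode,
    mean_vf_amplitude,
    overlay_pacing,
    run_detector,
)

episode = loop_episode(generate_vf_episode(VfModelParams(target_mean_amp_mv=0.5, seed=3)), 60.0)
vf_amp = mean_vf_amplitude(episode)
print(f"VF episode: mean amplitude {vf_amp:.2f} mV, looped to {episode.duration_s:.0f} s")

clean = run_detector(episode)
print(f"no pacing      : detected={clean.detected} t_detect={clean.t_detect_s:.2f} s "
      f"t_therapy={clean.t_therapy_s:.2f} s")

for ratio in (2.0, 7.0):
    spec = OverlaySpec(rate_ppm=60.0, ratio=ratio, pulse_width_ms=1.0, phase_s=0.4)
    res = run_detector(overlay_pacing(episode, spec))
    td = f"{res.t_detect_s:.2f} s" if res.detected else "-"
    print(f"spike {ratio:.0f}x VF   : detected={res.detected} t_detect={td}")
# A spike twice the VF amplitude leaves detection intact; at seven times the
# VF amplitude the threshold never recovers between pulses and VF is missed.
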