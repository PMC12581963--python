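"""Detection-percentage grid over pacing rate, sensed amplitude and pulse width.

A desk-scale version of the in-silico sweep: detection degrades with sensed
spike amplitude, and wider pulses are more harmful at equal sensed amplitude.
"""

from pacesense import generate_episode_library, run_grid

library = generate_episode_library(20, (0.15, 1.0), seed=1)
grid = run_grid(
    library,
    widths_ms=[0.24, 1.0],
    amps_mv=[0.0, 1.0, 2.5, 5.0],
    rates_ppm=[60.0, 90.0],
    seed=5,
)
print(f"baseline (no pacing): {grid.baseline_pct:.1f}% of {grid.n_episodes} episodes detected")
print(grid.to_frame().pivot_table(
    index=["rate_ppm", "pulse_width_ms"], columns="spike_amp_mv", values="pct_detected"
))
# Each cell is the percentage of episodes detected; the 0-mV column equals the
# baseline, and cells fall as spike amplitude or pacing rate rises.
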