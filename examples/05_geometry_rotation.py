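"""Implant geometry: rotation poses, distance sums and sensed spike amplitude.

In the volume-conductor model it is not the capsule's rotation angle but the
total electrode separation (D1 + D2) it creates that drives the sensed
artefact amplitude; the collinear trade-off shows why both distances cannot
shrink at once.
"""

from pacesense import PacingProgram, collinear_tradeoff, rotation_distance_sum, sensed_amplitude
from pacesense.geometry import pose_from_distances

program = PacingProgram(amplitude_v=3.0, pulse_width_ms=0.24)
poses = [(11.92, 7.23), (7.36, 12.79), (13.48, 16.58), (18.17, 26.64)]
print("D1 (mm)  D2 (mm)  D1+D2 (mm)  sensed amplitude (mV)")
for d1, d2 in poses:
    g = pose_from_distances(d1, d2)
    print(f"{d1:7.2f}  {d2:7.2f}  {rotation_distance_sum(g):10.2f}  "
          f"{sensed_amplitude(g, program):8.2f}")
print()
new_ring = collinear_tradeoff(16.0, 21.0, 10.0)
print(f"collinear trade-off: moving the tip 16 -> 10 mm pushes the ring 21 -> {new_ring:.0f} mm")
# Sensed amplitude falls monotonically with the distance sum, and the
# trade-off makes simultaneous proximity of both electrode pairs infeasible.
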