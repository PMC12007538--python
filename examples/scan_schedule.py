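"""Build the whole-brain scan schedule and print its timing.

Four 64-element arrays spaced 2.1 mm apart visit four motor positions
0.525 mm apart in the interleaved order 1-3-4-2, tiling 16 contiguous
coronal slices.  The printed TR (2.4 s) is the time for one full volume;
the maximum motor move (1.050 mm, two steps) bounds the translation dead
time between positions.
"""

from smsfus import ProbeGeometry, build_schedule, compound_frame_rate, max_cyclic_displacement

probe = ProbeGeometry()
schedule = build_schedule(probe, n_positions=4)

print(f"channels           : {probe.n_channels}")
print(f"TR                 : {schedule.tr_s:.1f} s")
print(f"slices             : {schedule.n_slices} at {schedule.step_mm:.3f} mm step")
print(f"visiting order     : {schedule.order}")
print(f"max motor move     : {max_cyclic_displacement(schedule):.3f} mm")
print(f"compound frame rate: {compound_frame_rate(4000, 8):.0f} Hz (4 kHz PRF / 8 angles)")
print()
print(schedule.to_frame().to_string(index=False))
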