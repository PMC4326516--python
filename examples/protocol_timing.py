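"""Timing arithmetic of the shipped GraSE protocol presets.

Prints, for each variant, the effective echo times, the refocusing-train
duration per excitation, the heartbeats needed per slice and the
resulting breath-hold at a typical heart rate, plus the black-blood
inversion delay the dual-IR module would use.
"""

from grasemap import (
    black_blood_inversion_delay,
    breath_hold_duration,
    echo_times,
    num_heartbeats,
    preset,
    preset_names,
    shot_duration,
)

RR = 985.0  # ms, ~61 bpm

for name in preset_names():
    p = preset(name)
    te = echo_times(p)
    print(f"{name:10s} echoes {p.n_echoes} (+{p.n_startup} start-up)  "
          f"TE {te[0]:.1f}..{te[-1]:.1f} ms  "
          f"shot {shot_duration(p):.1f} ms  "
          f"{num_heartbeats(p)} heartbeats  "
          f"breath-hold {breath_hold_duration(p, RR):.1f} s")

print(f"\nblack-blood inversion delay at RR {RR:.0f} ms: "
      f"{black_blood_inversion_delay(RR):.1f} ms (blood T1 1200 ms)")
# The 6Ec variant needs 13 heartbeats per slice (12 imaging shots + 1
# dummy), i.e. a ~12.8 s breath-hold at 61 bpm — one slice per hold.
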