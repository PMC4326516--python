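"""AHA 16-segment reporting on the worked healthy-volunteer example.

Aggregates the published-style segmental T2 values of one healthy
volunteer with the package's rule (global = unweighted mean of segment
means, population SD over segment means) and reports the regional
contrasts between slice levels and walls.
"""

import numpy as np

from grasemap.datasets import healthy_example_segments
from grasemap.segments import regional_contrasts, segment_report

seg = healthy_example_segments()
print(seg.to_string(index=False))

reports = {}
for level in ("basal", "mid", "apical"):
    sub = seg[seg["level"] == level]
    labels = np.repeat(sub["aha_id"].to_numpy(), 4).reshape(-1, 4)
    t2 = np.repeat(sub["t2_ms"].to_numpy(), 4).reshape(-1, 4)
    reports[level] = segment_report(t2, labels)

all_labels = np.repeat(seg["aha_id"].to_numpy(), 4).reshape(-1, 4)
all_t2 = np.repeat(seg["t2_ms"].to_numpy(), 4).reshape(-1, 4)
rep = segment_report(all_t2, all_labels)
print(f"\nglobal T2: {rep.global_mean:.1f} +/- {rep.global_sd:.1f} ms "
      "(mean +/- population SD of segment means)")

contrasts = regional_contrasts(reports)
print(f"slice means: " + ", ".join(
    f"{lv} {m:.2f}" for lv, m in contrasts["slice_means"].items()))
print(f"apical - mid:  {contrasts['apical_minus_mid']:+.2f} ms")
print(f"apical - basal: {contrasts['apical_minus_basal']:+.2f} ms")
print(f"septal - lateral: {contrasts['septal_minus_lateral']:+.2f} ms")
# Healthy myocardium is regionally homogeneous: global ~52 ms with
# slightly higher apical values, septal/lateral difference ~1 ms.
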