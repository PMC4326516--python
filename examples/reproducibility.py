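"""Synthetic scan/re-scan reproducibility of global myocardial T2.

Images five synthetic subjects twice with independent noise, runs the
full pipeline (cardiac phantom -> ML fit -> AHA segment report) for
each visit, and summarizes visit-to-visit agreement of global T2 with a
Bland-Altman analysis.
"""

from grasemap import interstudy_experiment, preset

subjects = [
    (52.0, 53.0, 51.0, 52.5, 51.5, 52.0),
    (50.0, 51.0, 49.5, 50.5, 50.0, 51.5),
    (54.0, 55.0, 53.0, 54.5, 53.5, 54.0),
    (51.0, 52.0, 50.0, 51.5, 50.5, 51.0),
    (53.0, 54.0, 52.0, 53.5, 52.5, 53.0),
]

for snr in (50.0, 20.0):
    res = interstudy_experiment(
        subjects, preset("6Ec"), snr=snr, seed=0, image_shape=(72, 72)
    )
    print(f"SNR {snr:4.0f}: mean difference {res.mean_diff:+.2f} ms, "
          f"95% LoA [{res.loa_low:+.2f}; {res.loa_high:+.2f}] ms, n = {res.n}")
# With identical underlying tissue the mean difference sits near zero;
# the limits of agreement widen as SNR drops.
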