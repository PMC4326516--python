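"""Effect of the refocusing slice profile on the measured T2.

Simulates the slice-integrated echo train of a T2 = 52 ms tissue (about
healthy myocardium) for the three refocusing profiles and mono-
exponentially fits each train: imperfect refocusing feeds stimulated
echoes into later echoes and inflates the fitted T2, and a start-up
echo (6Ec) absorbs most of the first-echo transient compared to the
variant without one (7Ec_no_se).
"""

from grasemap import echo_times, fit_pixel_lsq, preset, slice_profile_echo_train

T2_TRUE, T1 = 52.0, 1000.0

print(f"true T2 = {T2_TRUE} ms\n")
print(f"{'profile':15s} {'6Ec fit':>9s} {'7Ec_no_se fit':>14s}")
for profile in ("ideal", "slr_optimized", "suboptimal"):
    fits = []
    for proto in ("6Ec", "7Ec_no_se"):
        p = preset(proto).with_profile(profile)
        train = slice_profile_echo_train(T2_TRUE, T1, p)
        fits.append(fit_pixel_lsq(train, echo_times(p), mode="nonlinear")[1])
    print(f"{profile:15s} {fits[0]:8.2f}  {fits[1]:13.2f}")
# A suboptimal profile overestimates severely; the start-up echo pulls
# the fit back toward truth; the optimized profile is accurate either way.
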