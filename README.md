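# grasemap

Quantitative myocardial T2 mapping with gradient-spin-echo (GraSE)
imaging, as a reusable relaxometry toolkit.

Many acute myocardial conditions (infarction, myocarditis, takotsubo
cardiomyopathy) produce edema, and tissue water content maps directly
onto the transverse relaxation time T2. Breath-hold GraSE imaging
acquires a black-blood multi-echo series — a turbo-spin-echo train whose
every spin echo is read out with a short EPI train and reconstructed as
its own image at effective echo time TE_k = TE_1 + (k−1)·ΔTE — from
which a per-pixel T2 map is estimated. Healthy myocardium sits near
52 ms at 1.5 T; acute injury prolongs it into the 60–90 ms range.

`grasemap` implements the full quantitative chain:

- **Protocol timing** (`grasemap.protocols`): the four evaluated GraSE
  variants (`9Ec`, `6Ec`, `6EcLR`, `7Ec_no_se`) with echo times, shot
  duration, heartbeat/breath-hold arithmetic and the dual-inversion
  black-blood nulling delay TI = T1·ln(2/(1+e^(−RR/T1))).
- **Echo-train forward model** (`grasemap.epg`): extended-phase-graph
  simulation of the refocusing train under imperfect slice profiles.
  Flip angles below 180° divert magnetization into stimulated-echo
  pathways that decay with T1 instead of T2 and inflate late echoes —
  the mechanism behind T2 overestimation with suboptimal refocusing
  profiles, mitigated by a discarded start-up echo.
- **Noise model and estimator** (`grasemap.noise`, `grasemap.fitting`):
  magnitude images carry Rician noise (noncentral chi for a
  root-sum-of-squares phased-array combination with L channels). T2
  maps are produced by maximizing the likelihood
  Σ_k log f(m_k | S0·e^(−TE_k/T2), σ, L), which removes the noise-floor
  bias that plain least squares incurs on late, low-signal echoes.
- **Synthetic phantoms** (`grasemap.phantoms`): a six-tube MnCl₂-like
  phantom (T1 ≈ 10×T2) and a short-axis cardiac phantom with nulled
  blood pool and per-AHA-segment T2, rendered through the EPG forward
  model with seeded noncentral-chi noise.
- **Reference comparison** (`grasemap.cpmg`): dense 32-echo CPMG
  (ideal-refocusing) gold-standard fits and the GraSE-vs-reference
  correlation/calibration line.
- **Segmental analysis** (`grasemap.segments`): AHA 16-segment label
  maps from endo/epicardial contours and the RV insertion point;
  per-segment and global T2 (global = unweighted mean of segment means,
  population SD over segment means); regional contrasts.
- **Agreement statistics** (`grasemap.agreement`): Bland–Altman mean
  difference with 95% limits of agreement (±1.96·SD of differences) and
  a full synthetic scan/re-scan experiment.

## Worked example

`examples/echo_train_simulation.py` fits mono-exponentials to simulated
echo trains of a T2 = 52 ms tissue under the three refocusing profiles:

```
true T2 = 52.0 ms

profile           6Ec fit  7Ec_no_se fit
ideal              52.00          52.00
slr_optimized      51.99          52.05
suboptimal         57.97          73.70
```

With ideal or optimized refocusing the fit is accurate; a suboptimal
slice profile overestimates T2 severely, and the start-up echo of the
`6Ec` variant absorbs most of the transient (58.0 vs 73.7 ms).

`examples/segmental_report.py` aggregates the 16-segment worked example
of one healthy volunteer:

```
global T2: 51.6 +/- 3.3 ms (mean +/- population SD of segment means)
slice means: basal 49.15, mid 52.80, apical 53.45
```

`examples/phantom_recovery.py` runs the six-tube phantom end to end
(generation → pixelwise ML fit → CPMG reference comparison) and prints
per-tube T2 with `Pearson R = 0.999991, slope = 1.0068`;
`examples/reproducibility.py` runs the synthetic scan/re-scan
Bland–Altman experiment. A thin CLI mirrors these operations
(`grasemap protocol show 6Ec`, `grasemap simulate phantom ...`,
`grasemap fit ...`, `grasemap report ...`, `grasemap agree ...`).

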