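# trsaxs

Time-resolved small-angle X-ray scattering (TR-SAXS) analysis of
intrinsically disordered protein (IDP) ensembles, built around the
microfluidic mixing experiment: a protein stream (an α-synuclein-like
140-residue disordered chain) is flanked by two buffer/metal-ion streams in
a laminar co-flow channel, and 1-D scattering profiles I(q) recorded at
positions along the channel map to times after mixing. The package turns
such profile series — here generated by its own ground-truth-labelled
synthetic forward model, since the pipeline is exercised end-to-end without
external data — into conformational-ensemble kinetics.

It is aimed at structural biologists and SAXS practitioners who want a
scriptable, fully seeded re-implementation of the standard IDP TR-SAXS
stack: profile reduction, size descriptors, real-space inversion, ensemble
optimization, and downstream statistics.

## What it computes

- **Reduction** (`trsaxs.io`): 3-column `.dat` I/O, buffer subtraction with
  error propagation, inverse-variance frame averaging with a median-based
  outlier (radiation-damage) guard, common-q-range cropping.
- **Size descriptors** (`trsaxs.profiles`): Guinier fit
  `ln I = ln I₀ − q²R_g²/3` with automatic window selection
  (`q_max·R_g ≤ 1.1` by default); polymer-physics R_g for disordered chains
  via the Debye function `P(x) = 2(e^{−x} − 1 + x)/x², x = (qR_g)²`
  (optionally generalized with a Flory exponent ν); Kratky transform
  `q²I(q)`; mass fractal dimension from
  `log I = log I₀ − D_m log q` over `log₁₀ q ∈ [−1.4, −1.0]`; normalized
  forward-intensity trace I(0)/I(0)₀.
- **Real space** (`trsaxs.pddf`): regularized indirect Fourier transform to
  the pair-distance distribution p(r) (non-negative least squares with a
  second-difference penalty; L-curve choice of the regularization weight),
  with real-space R_g, I(0), and a Dmax scan.
- **Conformers** (`trsaxs.pool`, `trsaxs.debye`): pools of self-avoiding
  Cα chains (3.8 Å virtual bonds, hard-sphere excluded volume, mixed
  stiffness regimes spanning R_g ≈ 15–100 Å) and their theoretical profiles
  by the Debye formula `I(q) = Σᵢⱼ fᵢfⱼ sin(qr_ij)/(qr_ij)`, with a
  histogram-accelerated path accurate to <0.3% at 0.5 Å bins.
- **Ensemble optimization** (`trsaxs.eom`): a genetic algorithm selects a
  fixed-size sub-ensemble (50 members, repetition allowed) whose average
  curve best fits a target after closed-form scale/background fitting;
  reports reduced χ², conformer fractions, and R_g distributions.
- **Statistics** (`trsaxs.stats`): ensemble-weighted Cα–Cα domain distances
  (end-to-end 1–140, NTD 1–60, NAC 61–90, CTD 91–140, plus 1–90 and
  61–140); Ward-linkage clustering of standardized (R_g, R_ee, fraction)
  features cut at cophenetic distance t = 2.5; Kruskal–Wallis with Dunn
  post-hoc tests, Benjamini–Hochberg correction, and Hedges' g
  (`J = 1 − 3/(4(n₁+n₂)−9)`, |g| > 0.8 flagged).
- **Mixing model** (`trsaxs.mixing`): Fick diffusion times `t_D = y²/(2D)`,
  plug-flow position→time mapping `t = x·A/Q`, and the dilution plateau
  from the inlet flow balance.
- **Synthetic data** (`trsaxs.synth`): two-population (compact ≲35 Å /
  extended ≳45 Å) ensembles with exponential fraction kinetics f(t),
  dilution decaying to 1/3, counting-statistics noise, and matched buffer
  frames — every draw recorded as ground truth.

## Worked example

```sh
$ python analysis/01_mixing_model.py
mean axial velocity: 23.33 mm/s
  Mn: t_D = 1.82 s -> 42.4 mm downstream
  Fe: t_D = 2.07 s -> 48.2 mm downstream
  Cu: t_D = 1.71 s -> 39.8 mm downstream
  Zn: t_D = 1.75 s -> 40.8 mm downstream
full-channel residence time: 3.73 s
dilution plateau (equal thirds, center inlet): 0.333
```

Small ions cross the 50 µm half-channel in ~1.7–2.1 s, i.e. by ~40–48 mm
downstream — inside the 87 mm channel and the 3.64 s observation window —
and the fully mixed protein concentration settles at 1/3 of its inlet value
(equal three-way flow split), which is where the normalized forward
scattering I(0)/I(0)₀ plateaus.

```sh
$ python analysis/02_simulate_scenarios.py   # pool + 4 synthetic conditions
$ python analysis/04_ensemble_fit.py         # GA recovery of f(t)
  cu-like: median |recovered - f(t)| = 0.056 over 10 frames
  fe-like: median |recovered - f(t)| = 0.017 over 10 frames
  inert:   median |recovered - f(t)| = 0.050 over 10 frames
  wt-like: median |recovered - f(t)| = 0.032 over 10 frames
```

Each scenario plants an extended-population fraction trajectory
f(t) = f∞ + (f₀−f∞)e^{−kt} (e.g. the rapid-compaction condition collapses
from 0.60 toward 0); the GA, fitting every second frame against a shared
conformer pool, recovers it to within a few percentage points. The drivers
`03_profile_descriptors.py` (R_g / D_m / I(0) tables) and
`05_domains_clustering_stats.py` (domain distances, clustering, condition
tests) complete the per-figure analyses; all tables land under `results/`.

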