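# Methods

This note records the models, parameter choices, and numerical decisions
behind `trsaxs`, in the order data flows through the pipeline.

## Profiles and reduction

A profile is (q, I, σ) with q strictly increasing in Å⁻¹ and σ > 0
everywhere; zero or negative uncertainties are rejected at load because
every downstream fit is σ-weighted. Two-column files receive σ = 0.02·|I|
(configurable), a deliberately crude stand-in that keeps the math defined
without pretending to know the counting statistics. Buffer subtraction is
pointwise with σ propagated in quadrature; negative differences are kept —
clipping would bias the low-q region that Guinier fits see — and the profile
is flagged when more than 20% of points go negative. Frame averaging uses
inverse-variance weights; the outlier guard compares each frame to the
per-q **median** frame (a mean reference lets one damaged frame drag the
center and reject good frames) and drops frames whose median standardized
deviation exceeds 3. Time series are cropped to the intersection q-range so
all fits share one grid.

The default theoretical q grid is **log-spaced**, 101 points over
[0.005, 0.5] Å⁻¹. Linear spacing leaves fewer than five points inside
q·R_g ≤ 1.1 once R_g exceeds ~50 Å, making Guinier analysis of extended
ensembles impossible; log spacing mirrors how beamlines rebin low q and
still covers the fractal window and the Kratky tail.

## Radius of gyration

`guinier_fit` fits ln I on q² by σ-weighted least squares, shrinking the
window from above until q_max·R_g ≤ 1.1 is self-consistent. The 1.1 default
sits between the globular convention (1.3) and strict IDP practice (≈1.0).
A near-zero slope returns R_g < 1 Å with a `degenerate` flag instead of an
error.

One bias is worth stating precisely. For an ideal Gaussian chain the Debye
intensity expands as ln P(x) = −x/3 + x²/36 with x = (qR_g)², so a straight
Guinier line fitted out to x_max systematically underestimates the slope:
about −4.7% in R_g at q_max·R_g = 1.1, under 2% only for q_max·R_g ≲ 0.65.
This is a property of the estimator, not noise; tests assert it rather than
wish it away. `idp_rg` removes the bias for disordered chains by fitting
I₀·P(qR_g) directly over the wider window q·R_g ≤ 3 (exact on Debye input),
optionally with a Flory exponent ν via the generalized Gaussian-chain form
factor written with incomplete gamma functions (ν = 1/2 reduces to Debye).
A reduced χ² > 5 flags non-IDP (e.g. globular) input. On a two-population
mixture the q→0 slope measures the z-average of R_g², so ground-truth
comparisons use the z-average ensemble R_g.

## Fractal dimension

D_m is the negative slope of log₁₀I on log₁₀q over q ∈ [10⁻¹·⁴, 10⁻¹] Å⁻¹,
by unweighted ordinary least squares (a σ-weighted variant exists behind a
flag); points with I ≤ 0 are dropped first and at least five must remain.
Exact power laws are recovered exactly; D_m ≈ 1.5–2 indicates swollen to
ideal chains, →4 compact globules.

## Pair-distance distribution

p(r) lives on a uniform 101-point grid on [0, Dmax] with both endpoints
pinned to zero. The forward map is I(q) = 4π Σ Δr p(r_j) sinc(q r_j)
(trapezoid end-weights); the inverse problem is solved as non-negative least
squares on the stacked system [A/σ; √α D₂] with D₂ the second-difference
operator — an explicit, reproducible replacement for GNOM's perceptual
criteria that serves the R_g/Dmax uses made of it. α = "auto" picks the
maximum-curvature corner of the discrete L-curve over 15 log-spaced
candidates anchored to trace(AᵀA)/trace(D₂ᵀD₂). Real-space moments use the
continuous p(r) convention R_g² = ∫r²p dr / (2∫p dr) and I(0) = 4π∫p dr;
note that for idealized point scatterers this convention omits the
zero-distance self-pair mass, so a pure distance spike at d reads
d/√2, not the rigid-body d/2 — for continuous bodies (the real use case)
the convention matches the coordinate R_g, as the sphere oracle verifies to
<1%. `scan_dmax` ranks candidate Dmax values by χ² plus a small penalty per
extra oscillation of p(r) beyond the main peak.

## Conformer pool

Chains are Cα traces grown residue by residue: fixed 3.8 Å virtual bonds,
pseudo-bond (vertex) angle uniform in a regime-specific range, dihedral
uniform, and a 3.8 Å hard-sphere excluded-volume check against all
non-adjacent residues (50 placement retries, then chain restart, 100
restarts budget). Three regimes — flexible [65°, 145°], intermediate
[90°, 160°], stiff [120°, 175°], mixed 0.5/0.3/0.2 — give a pool whose R_g
spans below 25 Å to above 55 Å at n = 140, covering both the compact
(~30 Å) and extended (50–60 Å) populations the ensemble fit must resolve.
Rationale for a mixture rather than one regime: a single realistic
flexibility produces almost no conformers above 55 Å, and the optimizer can
only select what the pool contains. The generation core is numba-compiled;
one 10,000-chain pool builds in ~1 s and is bit-reproducible from its seed.
Domain pairs follow the α-synuclein convention (NTD 1–60, NAC 61–90, CTD
91–140); the 61–90 pair is treated as NAC-internal, and the scheme is
configurable since domain boundaries differ across the literature. R_g uses
unit masses (Cα trace only).

## Theoretical scattering

The Debye sum uses identical per-residue form factors: `point` (f ≡ 1) by
default — the ensemble fit has a free overall scale, so a constant
prefactor is unidentifiable — or `gaussian-dummy`
f(q) = exp(−q²w²/2), w = 3 Å, to mimic residue-level density falloff. The
histogram path bins the N(N−1)/2 pair distances at 0.5 Å and evaluates the
sinc kernel at the per-bin **mean** distance with a per-bin **variance**
(second-order Taylor) correction; this keeps the error below 10⁻⁴ relative
up to q = 0.5 Å⁻¹ while making a 10,000 × 101 profile matrix a ~20 s
computation. Refining the bins strictly reduces the error.

## Ensemble optimization

A chromosome is a multiset of `ensemble_size` = 50 pool indices (repetition
allowed — this is what makes reported fractions meaningful). Fitness is the
reduced χ² of the multiset-average curve after closed-form weighted fitting
of scale and constant background (K−2 degrees of freedom; K−1 with the
background off). Generational loop: elitism (top 5 of 50 copied), binary
tournament selection, per-slot uniform crossover (rate 0.5), per-slot
random-reset mutation (rate 0.1), up to 1000 generations with early stop
after 100 generations of <10⁻⁴ improvement. The initial population seeds
its first tenth with the best single-conformer ensembles (a cheap vectorized
screen of all lone conformers), which guarantees the final χ² never exceeds
the best single model and speeds convergence. Everything is reproducible
bit-for-bit from the settings seed.

Recovered-mass scoring: synthetic truths draw only from R_g < 35 Å
(compact) and R_g > 45 Å (extended) subpools, but the fitted ensemble may
select pool members inside the 35–45 Å band. Such members are attributed to
the nearer population, i.e. extended mass is the weight above the band
midpoint 40 Å; counting only >45 Å would undercount extended mass by
construction whenever the optimizer uses band conformers to interpolate.

## Downstream statistics

Weighted domain distances are Σ w_k d_k with w_k the ensemble fractions,
reported with weighted SDs; they are convex combinations of member
distances. Clustering standardizes (R_g, R_ee, fraction) per column,
applies Ward linkage on Euclidean distances, and cuts the dendrogram at
cophenetic distance t = 2.5. The threshold's units are those of the linkage
on standardized features; because Ward heights grow with sample size, the
cluster count at fixed t rises with the number of rows — k is therefore
reported, never forced, and t is configurable. Silhouette scores validate
the cut (undefined and flagged at k = 1). Cluster summaries
(mean R_g/R_ee, per-condition occupancy) are fraction-weighted by default.
Condition comparison: Kruskal–Wallis per feature; if p < α = 0.05, pairwise
Dunn z-tests on the pooled tie-corrected ranks; Benjamini–Hochberg
adjustment per feature family; Hedges' g with small-sample correction
J = 1 − 3/(4(n₁+n₂)−9) for every pair; pairs with q < α and |g| > 0.8 are
flagged. Dunn's test is implemented in-package (tie-corrected SE
√[(n(n+1)/12 − Στ/(12(n−1)))(1/n₁+1/n₂)]).

## Mixing model

Plug flow: v = Q/(w·d) = 23.33 mm/s at 14 µl/min in a 100 × 100 µm channel,
so position x maps to time t = x/v (parabolic-profile and Taylor-dispersion
corrections are out of scope). Fick time t_D = y²/(2D) with y = 50 µm;
stored diffusion coefficients (m²/s): Mn 6.88e-10, Fe 6.05e-10,
Cu 7.33e-10, Zn 7.15e-10, overridable per run. The post-mixing plateau of
I(0)/I(0)₀ equals the protein inlet's flow fraction (default 1/3 of three
equal inlets) by mass balance.

## Synthetic forward model

Each scenario fixes: an extended-fraction trajectory
f(t) = f∞ + (f₀−f∞)e^{−kt} (presets: wt-like 0.50→0.15 at k = 1/s, fe-like
0.60→0 at k = 2/s for rapid compaction, cu-like 0.70→0.40 at k = 0.8/s for
persistent elongation, inert constant 0.35); a dilution
c(t) = c∞ + (1−c∞)e^{−(t−t_lag)/τ} with c∞ = 1/3, τ = 0.8 s and a diffusion
lag t_lag = 0.4 s during which the channel center still holds the undiluted
protein (c ≡ 1 for t ≤ t_lag) — without the lag, normalizing by the first
frame at 0.18 s cannot reach a ≈1/3 plateau because the first frame is
already diluted, for any τ; a 20-point time grid at 0.18 s spacing ending
at 3.64 s (one frame per measurement position); and
counting-statistics-like noise σ(q) = ε·√(I(q)·I(0)) with ε = 0.01 (1%
relative error at the forward intensity, growing as I falls). Per frame a
finite 50-member ensemble is drawn with extended probability f(t) —
finite-sample draws, not exact mixture curves, so the optimizer has an
attainable discrete optimum — the average profile is scaled by c(t), noise
is added, and a matched noise-only buffer frame is emitted so the
subtraction stage is exercised. The draw seed and noise seed are separate:
changing only the noise seed leaves the ground truth (drawn multisets,
f, c, apparent R_g) bit-identical.

What the generator does **not** emulate: inter-particle structure factors,
aggregation or oligomer growth, radiation damage, detector artifacts,
q-dependent smearing, or any metal-specific scattering contrast. Passing
recovery tests therefore demonstrates that the analysis chain is correct
and well-calibrated on data obeying its own assumptions — not that those
assumptions hold for any particular experimental system.

## Problem sizes and runtimes

Default desk-scale sizes: 10,000-conformer pools (the recovery analyses'
reference scale; pool size is a flag), 50-member ensembles, 50 ensembles ×
≤1000 generations with early stop, 101-point q and r grids, 100-replicate
null calibration for the test battery. A full acceptance run
(`scripts/acceptance.py`) completes in well under a minute on one CPU; the
test suite runs in about a minute, dominated by the 10,000-chain pool and
its profile matrix.

## Known limitations

- The polymer R_g estimator is a Debye-function fit, not any specific web
  server's molecular form factor; on strongly non-Gaussian single
  conformers it reports a best-effort fit with a quality flag.
- The p(r) solver's L-curve corner can pick a slightly rough α on nearly
  noise-free data; the α grid and an explicit α are exposed.
- GA identifiability: at 1% noise, compositions differing by a few percent
  in band-adjacent mass produce curves within noise of each other; recovered
  fractions are accurate to roughly ±5 points per frame, which is the
  information the data contain, not an optimizer deficiency.
- The cluster threshold t = 2.5 has no absolute meaning across datasets of
  different size (Ward heights scale with n); compare k and silhouettes,
  not raw thresholds, across studies.
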