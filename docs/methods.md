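# Methods

This note records the model, the numerical choices and the known limits of
the package, in the order the analysis chain runs.

## Relaxation-time model

An impedance spectrum is modelled as a continuum of first-order relaxations,
Z(ω) = R∞ + R_p ∫ g(τ)/(1+jωτ) dτ with ∫g dτ = 1. The analysis axis is
x = ln τ with G(x) = τ·g(τ); the change of variables ∫G dx = ∫g dτ is exact
only in the natural logarithm, so **every internal log-time axis is base e**
and base-10 appears only in display labels. The model assumes a linear,
time-invariant sample over the acquisition (a few seconds), which holds for
small-signal EIS taken ≥ 1 min after a pulse train, when post-pulse dynamics
are slow.

## Inversion

The distribution is discretized into M step functions on a uniform ln τ grid
over [τ_inf, τ_sup]; bin j is evaluated at its log-midpoint τ_j and carries a
weight w_j = R_p G(x_j)Δx in ohms. Defaults: M = 120, τ ∈ [10⁻⁷, 10⁻¹·⁵] s —
a window that brackets the reciprocal band of a 20 Hz–400 kHz sweep by about
two decades on each side (a coverage warning fires otherwise).

Estimation solves

    min_{w ≥ 0}  ‖Z_meas − Z_model‖² + λ‖D₁w‖²

with real and imaginary parts stacked (weighting configurable, 1:1 default)
and R∞ as an extra regression column excluded from the penalty. Choices and
why:

* **Joint real/imaginary fit.** R∞ is identified by the real part; the top
  measured frequency is not asymptotic for the fastest tissue dispersions, so
  pinning R∞ to |Z| at 400 kHz would bias the short-time end.
* **Nonnegativity.** Physical relaxation strengths are positive; w ≥ 0 also
  acts as a strong regularizer. The problem stays convex and is solved with
  active-set NNLS on the augmented system [[A], [√λ·D₁]] — deterministic, no
  seed.
* **Penalty.** D₁ takes first differences of neighboring bin weights
  (discrete ‖g′‖² smoothing); boundary bins appear only in their single
  interior difference; the R∞ column is never penalized. λ defaults to 0.1,
  appropriate for sub-percent multiplicative noise on a ~1 kΩ spectrum.
* **λ selection.** `tune_lambda` scores a candidate ladder by GCV,
  `2N·RSS/(2N − df)²`, with df the trace of the active-set hat matrix. On
  well-fit data the GCV profile is nearly flat in λ (the residual is pinned
  at the noise floor over decades of λ); the choice between data-compatible
  solutions of different sharpness is then a prior, not something the data
  decide — see Limitations.

## Electrode separation

In 2-electrode measurements the electrode processes (double layer/charge
transfer, then ionic diffusion) occupy τ above ~2·10⁻⁴–6·10⁻⁴ s, well above
the tissue dispersions. `split_drt` cuts the weight vector at the bin
boundary nearest τ_max (default 6·10⁻⁴ s, the flat-brass value); the split is
hard — no apportioning of a straddling bin — because the procedure models a
visual threshold between non-overlapping clusters. R∞ goes wholly to the
tissue side, so `tissue_R0 = R∞ + Σ tissue weights` is the electrode-free DC
resistance. For needle-like electrodes whose charge-transfer peak overlaps
the tissue, `split_by_gaussians` fits the full distribution and attributes
components with μ ≥ τ_max (including their below-cut tails) to the electrode.
`suggest_tau_max` automates the threshold as the deepest interior minimum of
the 5-bin-smoothed curve in a search window, falling back to the window
midpoint with a warning. `geometry_rescale` multiplies a distribution by an
empirical cell-constant correction so 4-electrode references can be overlaid
on 2-electrode results; the factor is an input, not estimated.

## Gaussian decomposition

The tissue curve R_p·G(x) is fitted with K Gaussians in x; component k has
amplitude a_k (Ω per ln-τ unit), location ln μ_k and spread σ_k, and
contributes R_pk = a_k σ_k √(2π) to R₀ = R∞ + ΣR_pk (both identities are
verified against quadrature in the tests). Components are reported in
decreasing μ, matching the physical reading that processes reach steady state
from the fastest up as frequency falls.

Fitting is bounded trust-region least squares from a multi-start roster —
local maxima of the 5-bin-smoothed curve, quantiles of the cumulative mass,
and seed-controlled jitters of both; the lowest RSS wins, making the fit
deterministic per seed. Bounds: μ inside the fitted window; σ in
[max(0.05, 1.5·Δx), 3]. The lower σ bound is an identifiability floor: a
component narrower than ~1.5 grid bins (0.16 ln units at M = 120) cannot be
distinguished from the discretization and, if allowed, acts as a single-bin
noise absorber that corrupts model selection. The upper bound blocks
plateau-like components. Exactly coincident locations after convergence are
tie-broken by a 10⁻⁹ relative nudge so the ordering stays strict.

## Model selection

K is chosen by nested F-tests with
F = (RSS_{K−1} − RSS_K)/RSS_K × (n − 3K − 1)/3 against F(3, n − 3K − 1) —
three parameters per component, n the number of time bins entering the fit.
`select_K` fits K over a contiguous range, warm-starting each fit from the
previous one (so RSS is non-increasing by construction) and stops at the
smallest K whose increment to K+1 is insignificant at the chosen threshold
(default p > 0.05). When a `tail_cutoff` is given, the F sequence is
recomputed on bins with τ below the cutoff (n replaced by the tail bin
count) and drives the choice; short-time structure is otherwise washed out
by the full-range statistic.

Calibration caveats, measured on synthetic distributions:

* On the full 120-bin grid the test is strongly anticonservative — every
  increment looks significant — for two reasons: empty bins clipped at zero
  carry a positive bias a wide component can always "explain", and a new
  component may be placed anywhere, so the statistic behaves like a maximum
  over placements rather than a fixed 3-parameter test. Selection should
  therefore run on a window restricted to the distribution's support, with n
  of order a few tens of bins; there the realized error rate is close to
  nominal (the package's selection checks pass in ~19/20 noise seeds).
* The F-test assumes homoscedastic residuals; under strongly multiplicative
  noise it over-selects.

## Simulator

Forward elements: Debye R/(1+jωτ₀); RQ (Cole-Cole) R/(1+RQ(jω)^q) with the
closed-form distribution G(x) = (1/2π)·sin((1−q)π)/(cosh(q(x−x₀)) −
cos((1−q)π)), validated against the forward relaxation integral to ~10⁻¹³
before anything relies on it; log-normal dispersions evaluated by 120-node
Gauss–Hermite quadrature (≤10⁻⁸ relative error, cross-checked against a
10⁵-node trapezoid); and a finite-length (tanh) Warburg for electrode
diffusion, chosen over the semi-infinite form so the synthetic spectrum has
a finite DC limit and the generator stays well-posed. All elements satisfy
Z(0) = R and Z → 0 at infinite frequency.

The `potato_model` preset emulates a ~1 kΩ, 2-electrode plant-tissue sample:
R∞ = 150 Ω; six log-normal tissue dispersions — α at 3·10⁻⁴ s (39 Ω), three
β components at 2·10⁻⁵/6·10⁻⁶/2·10⁻⁶ s (221/270/266 Ω, σ = 0.40; the spread
reflects variable cell size and starch content), starch at 4·10⁻⁷ s (139 Ω,
σ = 0.30) and a nucleus component at 1.5·10⁻⁷ s (26 Ω, σ = 0.25), at the
short-time edge of the analysis grid as organelle dispersions are; electrode
charge transfer as an RQ element at 5·10⁻³ s (600 Ω, q = 0.9 — flat brass
contacts show a narrow, visually separable charge-transfer peak) and slow
diffusion as a Warburg with τ_d = 0.5 s (800 Ω). Noise is multiplicative
i.i.d. Gaussian applied independently to the real and imaginary parts
(default 0.5%), reproducible per seed. What the preset does **not** emulate:
correlated instrument noise, drift during stabilization, inductive artifacts,
sample-geometry fringing, and any frequency dependence of the electrode
elements' parameters.

Cell-scale anchors for choosing time constants: the membrane-polarization
constant r·C_m·(1/σ_c + 1/2σ₀), optionally with the double layer in series
(C_m/(1 + C_m/C_dl)) and with the cytoplasm conductivity diluted by
insulating starch spheres via Maxwell–Garnett, σ_eff = σ_c(1−p)/(1+p/2) —
at p = 0.75 the β time constant grows ~4–5×, consistent with heavily
starch-loaded cells relaxing slower; and the counterion constant r²/(2ukT).

`generate_ep_dataset` emulates a pulse-protocol study: per replicate the
baseline is jittered log-normally (default CV 10%, emulating sample
heterogeneity), a pre spectrum is drawn, the field level's effect profile is
applied, and a post spectrum is drawn. The reversible profile shifts the β
time constants (membrane surface-state perturbation) while leaving every
element resistance — hence R₀ — exactly unchanged; the irreversible profile
multiplies the α/β/starch resistances by 0.3 (leaky membranes, stripped
double layers) and leaves the nucleus untouched.

## Monitoring

`compare_pair` runs inversion → split → K-Gaussian fit on both spectra after
rescaling **both** by R_ref/R₀(pre) — the pre-pulse tissue DC resistance only,
so genuine post-pulse changes survive normalization (R_ref defaults to
1000 Ω). Components are matched across the pair by rank of μ; mismatched
counts truncate to the smaller K with a warning. The call is "reversible"
when |R₀ ratio − 1| ≤ 10% and at least one component moved by more than 0.1
ln units, "irreversible" when the ratio drops below 0.9, else "none". The
10% tolerance sits between the few-percent DC drift of reversible pulses and
the multi-fold drop of irreversible ones; it is configurable and echoed in
the comparison metadata. `field_sweep` aggregates comparisons per field level
and reports, per component, the lowest field whose mean post-pulse R_pk falls
below (1 − tolerance) of its pre-pulse mean.

## Thermal bounds

Rectangular-pulse heating is bounded with closed forms: absorbed energy
U·I·nΔt; sample heat capacity ρc_p·π(d/2)²h (defaults ρ = 1062 kg/m³,
c_p = 3770 J/kg/K, 10 mm × 4.5 mm); the **adiabatic** temperature rise E/C —
an upper bound, and labelled as such, since the electrodes conduct heat away;
the diffusion time l²ρc_p/k (k = 0.55 W/m/K) over half the sample height;
and the relative conductivity change α_T·ΔT with α_T between 0.025/K (intact)
and 0.03/K (damaged tissue). For the standard 8 × 100 µs train at 450 V/12 A
these give 4.32 J, 1.42 J/K, 3.05 K, 36.9 s — heating perturbs conductivity
by at most a few percent and cannot explain multi-fold DC-resistance changes.

## Problem sizes and determinism

The test suite and the acceptance script run the full chain at the study
scale — 300-point spectra, M = 120, 6-component fits — with 20 independent
noise seeds for each stochastic claim; the whole suite completes in a few
minutes on one CPU. The inversion is seed-free (convex); Gaussian fitting
and the generators take explicit seeds, and every randomized script derives
its child seeds from a single `--seed` argument.

## Limitations

* **Resolution of the inversion is noise-limited, and component-level truth
  is not recoverable from the smoothed distribution at the default penalty.**
  With 0.5% noise, solutions of very different sharpness fit the data equally
  well; the penalized inversion returns the smoothest of them, which merges
  the three β components into a hump with shoulders. A 6-Gaussian refit of
  that curve recovers the *total* tissue R₀ to ~2–3%, but individual μ_k and
  R_pk can be off by tens of percent to several-fold, and the fit's preferred
  component allocation need not match the generating one. Tracking
  *changes* in the decomposition (the monitoring use case) is robust; reading
  absolute per-compartment parameters from a single decomposition is not.
* The α region is contaminated by whatever electrode charge-transfer tail
  lies below τ_max, and components at the short-time grid edge (nucleus) are
  partially degenerate with R∞ because their relaxation lies at or beyond the
  top of the measured band — both inflate component-parameter errors there.
* The F-test calibration depends on the fitting window (see Model selection).
* The Warburg element is handled by the Debye-kernel inversion only in the
  sense that its pole expansion lands at long τ; a diffusion-kernel analysis
  would represent it more compactly and is out of scope.
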