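# tissuedrt

Distribution-of-relaxation-times (DRT) analysis of tissue impedance spectra,
built for monitoring electroporation.

## The problem

Electrical impedance spectroscopy (EIS) measures a tissue's complex impedance
Z(ω) over a frequency sweep. In tissue the interesting physics — the α
dispersion of membrane-surface counterions, the β dispersion of cell-membrane
(Maxwell–Wagner) polarization, dispersions of starch granules and nuclei —
overlap each other in the frequency domain, and in a 2-electrode setup they
are buried under electrode polarization. The DRT re-expresses the spectrum on
a relaxation-time axis,

    Z(ω) = R∞ + R_p ∫ g(τ) / (1 + jωτ) dτ,      ∫ g(τ) dτ = 1,

where R∞ is the high-frequency resistance and R_p the total polarization
resistance. On a log-time axis (G(x) = τ·g(τ), x = ln τ) the slow electrode
processes separate cleanly from the tissue response and can be removed with a
simple threshold τ_max. The tissue part of R_p·G(x) is then decomposed into K
Gaussian components (log-normals in τ); component k contributes

    R_pk = a_k σ_k √(2π),        R₀ = R∞ + Σ_k R_pk

to the DC resistance, so each tissue compartment's share of R₀ can be tracked
through an electroporation protocol: reversible pulses shift component time
constants while R₀ stays put; irreversible pulses collapse the membrane
components and R₀ with them.

The estimation chain is:

1. **Inversion** — discretize g on M log-spaced bins of τ and solve the
   nonnegative ridge problem
   `min_{w≥0} ‖Z − Z_model‖² + λ‖D₁w‖²` (first-difference smoothing, R∞ as an
   extra unpenalized regressor); convex, deterministic.
2. **Electrode separation** — hard cut of the distribution at τ_max
   (6·10⁻⁴ s for flat brass electrodes), or component-based removal when the
   electrode peak overlaps.
3. **Decomposition** — multi-start least-squares fit of K Gaussians in ln τ;
   K chosen by nested F-tests,
   `F = (RSS_{K−1} − RSS_K)/RSS_K × (n − 3K − 1)/3`,
   optionally restricted to the short-time tail where new components matter.
4. **Monitoring** — paired pre/post analysis with rescaling to a reference
   R_ref = 1000 Ω, component matching by rank of τ, and a
   reversible/irreversible call from the R₀ ratio and component shifts.

A built-in simulator provides analytic oracles (Debye, RQ/Cole-Cole with its
closed-form DRT, log-normal, finite-length Warburg) and a noisy 2-electrode
"potato" preset for end-to-end testing, plus order-of-magnitude thermal
checks for pulse protocols.

## Worked example

```sh
tissuedrt simulate --preset potato --noise 0.005 --seed 7 --out spec.csv
tissuedrt drt --in spec.csv --out drt.csv --lambda 0.1
tissuedrt separate --in drt.csv --tau-max 6e-4 --mode cut --out tissue.csv
tissuedrt decompose --in tissue.csv --k 6 --out model.json
tissuedrt thermal --u 450 --i 12
```

prints

```
wrote spec.csv (tissue R_0 = 1111 ohm)
R_inf = 146.1 ohm, R_p = 1803 ohm, R_0 = 1949 ohm
tissue R_0 = 1134 ohm (electrode R_p = 815 ohm)
K = 6, R_0 = 1138 ohm
absorbed energy      = 4.32 J
heat capacity        = 1.42 J/K
adiabatic rise bound = 3.05 K (upper bound)
diffusion time       = 36.9 s
```

Reading the numbers: the raw 2-electrode inversion sees R₀ ≈ 1.95 kΩ, of
which ~0.8 kΩ is electrode polarization; cutting at τ_max = 6·10⁻⁴ s leaves a
tissue DC resistance of 1.13 kΩ, within ~2% of the generator's ground truth
(1.11 kΩ). The 6-component fit reproduces that total and apportions it among
the compartments (`model.json` holds each a_k, μ_k, σ_k, R_pk). The thermal
lines bound the heating of a 10 mm × 4.5 mm sample under 8 × 100 µs pulses at
450 V / 12 A: ≈ 4.3 J absorbed, ≈ 3 K adiabatic upper bound on the rise, and
a ~37 s thermal diffusion time.

The same chain is available as a library:

```python
import tissuedrt as td

model = td.potato_model(noise_sigma=0.005, seed=7)
spectrum = td.generate_spectrum(model)
drt = td.solve_drt(spectrum)                       # nonnegative ridge inversion
tissue = td.split_drt(drt, 6e-4).tissue_drt        # strip electrode polarization
fit = td.fit_gaussians(tissue, K=6, tau_window=(1e-7, 6e-4), seed=7)
print(fit.R_0, fit.R_pks)
```

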