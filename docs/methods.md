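# Methods

## Model

`vbdm` simulates a single-species host–phage–nutrient loop in a
well-mixed parcel of sub-ice ocean water or brine. Three state variables
evolve per unit volume: dissolved organic matter `N` (µg mL⁻¹),
heterotrophic bacteria `B` (cells mL⁻¹) and lytic viruses `V`
(cells mL⁻¹):

```
dN/dt = −α·N/(N+Q)·B + g·α·N/(N+Q)·B + n·γ·ϕ·V·B·w   [+ E(t), open mode]
dB/dt =  µ·N/(Q+N)·B − ϕ·V·B − d·B
dV/dt =  γ·β·ϕ·V·B − ϕ·V·B − m·V
```

Bacteria take up DOM with Monod kinetics (uptake constant `α`,
half-saturation `Q`), return a fraction `g` of gross uptake as exudate,
grow at rate `µ·N/(Q+N)`, die at background rate `d` and are infected at
the mass-action rate `ϕ·V·B`. Each lysed cell releases `β` virions and
`w = 10⁻⁷ µg` of DOM, of which a fraction `n` re-enters the pool; `γ`
weights lytic activity (γ = 1 is fully lytic — it multiplies viral
production in the equations, so larger γ means more lysis). Free
viruses decay at specific rate `m`.

The only temperature dependence is the Q10 law on the uptake constant:
`α(T) = 1.2×10⁻⁷ · 3^((T−23)/10)` µg cell⁻¹ hr⁻¹, appropriate for
psychrophilic metabolisms between −4 and 0 °C (α ≈ 7.7×10⁻⁹ at −2 °C).

**Closed mode** (a brine pocket sealed in the ice shell) has a finite
initial DOM pool: every run eventually starves, and the question is how
the boom–bust cycling and system lifetime depend on the parameters,
burst size above all.

**Open mode** (a sub-ice biosphere) adds a DOM source to the first
equation, `E(t) = f·(α/µ)·d·B(t)`: `α/µ` is the DOM-per-cell conversion
(µg cell⁻¹), so `(α/µ)·d·B` is the organic-matter equivalent of the
bacteria lost to non-viral death — matter that would sink out of the
layer as particulate material. The dimensionless elevator factor `f`
scales how much of that loss an upward, lysis-liberated DOM flux (the
"viral elevator" from a benthic chemosynthetic biosphere) replaces. `E`
is implemented state-dependently rather than as a constant; the per-run
*reported* E is its time average, which for a statistically steady run
is indistinguishable from an equivalent constant influx.

## Parameters

| symbol | field          | default | units            | note |
|--------|----------------|---------|------------------|------|
| N_i    | `N_i`          | 30      | µg mL⁻¹          | sampled 10–50 |
| B_i    | `B_i`          | 10⁵     | cells mL⁻¹       | sampled 10⁴–10⁶ (log) |
| V_i    | `V_i`          | 10⁶     | cells mL⁻¹       | sampled 10⁵–10⁷ (log) |
| T      | `T`            | −2      | °C               | sampled −4–0 |
| α_ref  | `alpha_ref`    | 1.2×10⁻⁷| µg cell⁻¹ hr⁻¹   | at 23 °C |
| µ      | `mu`           | 0.024   | hr⁻¹             | sampled 0.016–0.032 |
| Q      | `Q`            | 0.022   | µg mL⁻¹          | fixed |
| d      | `d_death`      | 2×10⁻⁴  | hr⁻¹             | fixed |
| m      | `m_decay`      | 0.015   | hr⁻¹             | fixed; see chain below |
| g      | `g_exudate`    | 0.09    | —                | sampled 0.02–0.2 (log) |
| n      | `n_recycle`    | 0.99    | —                | fixed |
| γ      | `gamma`        | 1       | —                | sampled 0–1 |
| ϕ      | `phi`          | 10⁻¹⁰   | mL cell⁻¹ hr⁻¹   | sampled 10⁻¹¹–10⁻⁹ (log) |
| β      | `beta`         | 250     | virions/cell     | sampled 10–500 |
| f      | `f_elevator`   | —       | —                | open mode; sampled 70–85 |

Sampling scale is log-uniform for every range spanning two or more
decades (B_i, V_i, ϕ, g) — each decade equally likely — and uniform for
the narrow ranges. The fixed worked-run setting (N=30, B=10⁵, V=10⁶,
T=−2, g=0.09, µ=0.024, γ=1, ϕ=10⁻¹⁰) is used by the single-run presets
and the acceptance checks.

Two cell-to-DOM conversions coexist deliberately: the lysis release
`w = 10⁻⁷ µg cell⁻¹` inside the dynamical equations, and
`6×10⁻⁸ µg cell⁻¹` in the biofilm-flux conversion of the habitability
chain. They originate from different observational bases and are kept
separate (fields `lysis_mass` and `dom_per_cell`); reconciling them is
out of scope.

## Numerics

The system is stiff — populations swing over seven or more orders of
magnitude per cycle — and is integrated with adaptive LSODA at
`rtol = 10⁻⁸`, `atol = 10⁻¹²` (state units). At these settings the
exact first integral `N + (α(1−g)/µ)·B` (valid when ϕ = d = 0) drifts
by < 10⁻⁴ relative over 20,000 h, and a fixed-step RK4 oracle at
h = 0.02 h matches the adaptive solution to < 0.1 % over the worked
run's first 2000 h. Ensembles integrate at `rtol = 10⁻⁶`,
`atol = 10⁻¹⁰`: individual trajectories in the oscillatory regime are
chaotic-sensitive to tolerance, but the run-level statistics
(retained fraction, averaged VBR and E) are tolerance-insensitive, and
the looser setting roughly halves the cost.

Tiny negative excursions (below 10⁻⁸ in state units, from interpolation
near zero) are clamped to zero on output; larger ones abort the run
with a diagnostic naming the parameter set. Open-mode ensemble runs
whose DOM exceeds 100× its initial value are terminated at the crossing
and removed as runaway: an oversupplying elevator grows DOM without
bound, the trajectory only gets stiffer, and its non-steady verdict is
already decided.

## Per-run metrics

* **Peak detection** operates on log₁₀ of a population series:
  a local maximum counts if it has prominence ≥ one decade (a factor 10)
  and exceeds 10 cells mL⁻¹. Both guards keep numerical ripple near
  extinction from registering. The published peak-timing statements are
  "~" values; detection conventions of this kind are a choice, and ours
  is stated here rather than inherited.
* **Inter-peak interval** is the mean spacing of successive bacterial
  peaks (NaN below two peaks).
* **Longevity** is the last time *both* populations exceed the
  1 cell mL⁻¹ viability floor. The viral population collapses first
  (once B falls below m/((γβ−1)ϕ) viruses cannot replace their decay),
  after which bacteria linger in slow exponential decline at rate d —
  a tail that persists tens of thousands of hours after the coupled
  dynamics have ended. Requiring both populations marks the death of
  the *system*: at the worked setting with β = 500 this gives
  ≈ 24,000 h, and longevity grows monotonically with burst size.
  A bacteria-only floor would instead measure the decay tail.
  Populations legitimately dip far below the floor mid-cycle (B to
  ~60 mL⁻¹, V to ~0.1 mL⁻¹), so the *last* crossing is used, never the
  first.
* **Steady state** (open runs): the mean DOM over the last 20,000 h
  window is within 10 % of the mean over the first 20,000 h window, and
  B stays above the floor throughout the last window. Default open-run
  duration is 200,000 h; closed runs default to 25,000 h and, having a
  finite DOM pool, always classify non-steady when run long enough to
  be classified at all.
* **Averaged VBR / E**: time averages over the full run; VBR samples
  with B = 0 are excluded; E is averaged by trapezoidal quadrature.

## Ensembles

Each run draws an independent RNG substream from
`(master_seed, run_index)`, so results are bit-reproducible and
order-independent. Closed-mode removal: integration failure or
undefined VBR. Open-mode removal additionally: DOM runaway and
non-steady classification. Tightening the drift limit can only shrink
the retained set.

The retained averaged-E sample is fitted with a log-normal (closed-form
MLE on log E; quantiles from the fitted CDF). The retained VBR sample
is summarized by quartiles. At the study sampling ranges only a few
per cent of open runs are steady: the elevator factor band that
balances a given parameter draw is narrow, so most draws drift or die.
Published statistics at the 2500-run scale: median VBR 4.7×10⁴ with
quartiles [891, 5.8×10⁵], and a fitted 90th percentile of E near
1.2×10⁻³ µg mL⁻¹ hr⁻¹; the test suite checks a down-scaled ensemble
(800 runs) of the same conditions against the published interquartile
band and factor-level tolerances.

## Habitability chain

Pure scalar arithmetic with explicit units (`vbdm.elevator`):

* `τ_diff = L²/C` — DOM diffusion time through a stagnant freshwater
  layer (L = 107–8000 m, C = 0.5×10⁻⁹ m² s⁻¹ → ~7×10⁵–4×10⁹ yr,
  Julian years). `convective_depth_limit` computes the thickness whose
  diffusion time equals the slow end of the 1–100 kyr ice-convection
  timescale — ~40 m with these inputs. (A literature threshold of
  ~800 m circulates for this comparison; it is not self-consistent with
  these inputs — 800 m gives 4×10⁷ yr — so the package computes the
  value rather than quoting one.)
* `ϕ = (L_B/24)/V_C` — infection rate from a 7 % d⁻¹ lysed fraction and
  2×10⁷ viruses mL⁻¹ → 1.46×10⁻¹⁰, used at one significant figure
  (10⁻¹⁰) as the model default.
* `m` — areal sediment viral decay (5.26×10¹² m⁻² d⁻¹) referred to the
  standing stock of a 1 cm × 10⁴ cm³ sample at density 1 g cm⁻³
  (abundance 1.5×10⁹ g⁻¹) → 0.0146 hr⁻¹, used as 0.015. The density is
  an explicit input because the derivation silently assumes it.
* `B_R = r·G·c·10⁻³` — benthic biomass synthesis from the H₂ flux
  (10¹⁰ mol yr⁻¹), the H₂+½O₂ free energy (237.13 kJ mol⁻¹) and an
  anabolic conversion of 1 g per 4.1868 kJ → 5.66×10⁸ ≈ 6×10⁸ kg yr⁻¹.
* `E(B_R, depth) = (B_R/b_m)·n_DOM/8760 / (4πr²·depth·10⁻³·10⁶)` — the
  per-volume DOM flux delivered to a global biofilm shell;
  1.45×10⁻³ µg mL⁻¹ hr⁻¹ at B_R = 6×10⁸ and 0.1 mm. E ∝ 1/depth
  exactly, so a cell of the feasibility map is sustainable iff the
  delivered flux meets the ensemble's steady-state demand quantile, and
  infeasibility propagates toward thicker biofilms: the contour
  `depth = k·B_R/E_quantile` is the thickest sustainable biofilm, of
  order 0.1 mm at the estimated B_R.

## What the generator does and does not emulate

The synthetic conditions are a single host and a single phage type with
fixed kinetics, spatially well mixed, with temperature entering only
through α. Real sub-ice or brine communities would have multiple
genotypes (smoothing the deep boom–bust cycles), dormancy and
lysogeny switching, temperature dependence in ϕ, β and µ, and
additional DOM sources and sinks. Passing tests therefore validate the
model's internal dynamics and the package's reproduction of the
published calculation chain — not the fidelity of any of those
simplifications to a real ocean world.

## Problem sizes used by the test suite

Single-run checks integrate 2,000–45,000 h at the default tolerances.
The open-ensemble check uses 800 runs of 200,000 h at the ensemble
tolerances with master seed 20; the acceptance script's targets are
deterministic single runs and scalar arithmetic. The full 2500-run
experiment is available as the `open-ensemble` preset
(`vbdm preset fig7 --seed 1`) and completes in well under an hour on
one core.

## Known limitations

* The steady-state filter inherits the published windows (20,000 h,
  10 %); the published outlier counts (31/300 closed, 2342/2500 open)
  used criteria that were never fully specified, so retained *counts*
  are reproduced only approximately even though the filter definition
  matches where stated.
* γ is a static lytic weight; the γ = 0 limit (no viral production but
  continued infection losses) represents fully lysogenic activity only
  crudely.
* The elevator factor f for a *specific* parameter draw is found by
  bisection on DOM drift (`find_steady_f`); steady f values are not
  unique and the helper makes no claim of matching any particular
  published digit string.
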