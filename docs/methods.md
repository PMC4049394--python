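# Methods

This note documents the models, the design procedures, the numerical choices
and the known limitations of `geneclock`. It states only what the shipped
tests and `scripts/acceptance.py` actually compute.

## Gate model

Each gene is modelled at one of two resolutions:

* **Two-stage**: `dm/dt = α f(u) − λ m + α₀`, `dp/dt = β m − γ p` with mRNA
  `m` and protein `p`.
* **Reduced (default)**: because mRNA is short-lived relative to protein, the
  mRNA stage is adiabatically eliminated: `dp/dt = ρ f(u) − γ p + ρ₀` with
  `ρ = αβ/λ`, `ρ₀ = α₀β/λ`. Both share the same steady states; the reduced
  model discards the mRNA relaxation time (≈ 1/λ) — a point that matters for
  the counters, see below.

The promoter activity `f` is one of seven Hill-ratio logics (NOT, Buffer,
AND, OR, XOR, NAND, NOR). Activities are exact algebraic complements
(`f_NOT + f_Buffer = 1`, `f_NAND = 1 − f_AND`, `f_NOR = 1 − f_OR`,
`f_XOR = f_OR − f_AND`); the property suite asserts these to 1e-12. Hill
ratios are evaluated by limit at `u = 0` (avoiding `0^n` issues for
non-integer `n`) and capped at 1e150 against overflow; regulator levels are
clamped at zero inside the compiled ODE so solver undershoot cannot produce
complex powers. Concentrations are dimensionless arbitrary units, time is in
seconds, and all worked examples use `n = 4`.

## Oscillator and the regulation coefficient χ

The repressilator template builds three NOT gates in a ring with synthesis
0.6851, decay 0.233, `K = 1`, `n = 4` and initial concentrations
(0.7, 1.2, 1.7). A regulation coefficient χ tunes the period. Two readings
of "χ scales the kinetics" are implemented:

* `chi_mode="rhs"` (default): χ multiplies the entire right-hand side
  (equivalently both ρ and γ). This is a pure time rescaling, so
  `period(χ) · χ` is constant and amplitude is χ-independent; the sweep test
  verifies both.
* `chi_mode="synthesis"`: χ multiplies synthesis only, changing the
  synthesis/decay balance.

The default was fixed by an empirical calibration: at χ = 0.5 the "rhs"
reading oscillates with period 32.3 s, amplitude 0.6345 and trajectory range
[0.63, 1.90] — the reference behaviour for the whole pipeline — whereas the
synthesis-only reading at χ = 0.5 collapses to a fixed point (residual swing
≈ 1.5e-4), which cannot serve as a clock source.

### Base level

`measure_amplitude_base` reports amplitude as half the steady peak-to-trough
swing and the **base level as the 50 %-duty level** (the time-median of the
steady window): the level a thresholding stage would use to produce a
square wave of exactly 50 % duty, which is the operational role the base
level plays in clock-pulse design. For a symmetric waveform this coincides
with the mid peak-trough level; for the skewed repressilator waveform they
differ noticeably (median 1.189 vs mid-range 1.265 at χ = 0.5). Duty cycles,
by contrast, are measured against the mid-range threshold (midpoint of
steady min/max) — symmetric and parameter-free — with one refinement: a
signal whose swing is below 5 % of its level is reported as constant-high
(duty 1.0), which distinguishes a rectified DC output with ripple from a
pulse train.

## Waveform shaper

A cascade of Buffers sharpens the oscillation into a square pulse. Stage 1's
Hill constant is the duty-cycle threshold; stage k ≥ 2 thresholds at the
half-maximal output of its predecessor, `K_k = (ρ_{k−1}+ρ_{0,k−1})/(2γ_{k−1})`
(0.5 for unit rates). The operating-point gain `ρn/(4γK)` is reported per
stage; gains ≤ 1 are warnings, not errors — a high-threshold first stage
(e.g. K = 1.76, gain ≈ 0.57) still *selects* the duty cycle correctly while
the downstream stages (gain 2.0) do the sharpening. A final compensation
Buffer with `ρ = γ·target/f_Buffer(input_high)` restores the logic-high
level; its feasibility requires the logic-high input to exceed the stage
threshold.

Two threshold-selection routes are exposed and neither is asserted as the
other's substitute:

* `analytic_threshold`: `y_T = y_d0 + A cos(πD)`, exact for a sinusoid. The
  evaluation takes the two instants symmetric about the sinusoid's peak time
  (`ω₀t_h + φ = π/2`, `t_h ∈ [0, T₀)`), the only reading under which a single
  threshold results.
* `empirical_threshold`: the (1 − D) time-quantile of a simulated steady
  trace, exact for any periodic waveform up to grid resolution.

**Measured duty vs design target.** The repressilator waveform is not
sinusoidal, and the cascade's own stage lag (one decay time per stage)
reshapes narrow pulses. With the reference narrow-pulse design
(first threshold 1.76) the measured steady duty of the final stage is
13.6 %: the oscillator spends 18.3 % of each cycle above 1.76 and the
cascade narrows this to 13.6 %. The closed-form sinusoidal threshold
(1.772) gives 12.6 % and the exact time-quantile threshold (1.855)
over-narrows to 6.4 % — for narrow pulses no single-threshold choice lands
exactly on 10 % through this cascade. Mid and wide targets are much better
behaved: measured duties are 48.8 % for a D = 0.5 design, 89.5 % for the
reference wide-pulse design (threshold 0.6761) and a clean 100 % (ripple
≈ 1.5 %) for the DC design. The duty tests assert exactly these behaviours:
monotonicity in D, ±3 pp accuracy at D = 0.5, and the reference designs'
measured values.

## Flip-flops and counters

The rising-edge JK flip-flop is six genes: `W = AND(K, CLK)`,
`V = AND(J, CLK)`, `R = AND(W, Q)`, `S = AND(V, Q̄)` and the NOR latch
`Q = NOR(R, Q̄)`, `Q̄ = NOR(S, Q)`. Driven by a narrow clock pulse it
reproduces the full JK truth table (hold/reset/set/toggle) against a digital
oracle. Latch state is seeded `Q = 0`, `Q̄ = ρ/γ` (its maximal level), all
other species 0; this is a design choice (overridable) that starts the latch
in a consistent logic state.

The falling-edge variant uses six NAND gates with the latch lines
`Q = NAND(S, Q̄)`, `Q̄ = NAND(R, Q)`, exactly as the canonical equations are
written. Boolean analysis of this two-layer 2-input-NAND topology shows it
is *not* a complete JK flip-flop: with the clock at rest (high) the latch
inputs are `R = ¬Q`, `S = ¬Q̄` — continuously active — so `J = K = 0` drives
both outputs high instead of holding, and the double inversion through W/V
swaps the set/reset roles. Only the `J = K = 1` toggle behaves as a JK
element, and that is the only mode in which the counters exercise it
meaningfully (the mod-3 counter always drives it with complementary J/K).
The test suite asserts the toggle behaviour and documents the rest; the
equations are kept as written rather than silently "repaired", since the
intended topology cannot be reconstructed from the equations alone.

### Interconnect race and relay Buffers

The counter wiring feeds flip-flop outputs directly into the next
flip-flop's J/K inputs (`pJ2 = pK2 = pQ1`). In continuous kinetics this has
a race condition: with uniform parameters (ρ = γ = 1, K = 0.5, n = 4) the
first flip-flop's Q collapses about 2 s into the ~4 s clock pulse, so the
second latch's toggle drive dies while its state sits at ≈ 0.47 — just short
of the 0.5 separatrix — and falls back. Division by 2 works; division by 4
and the mod-3 count do not, under direct wiring. This was probed across
pulse widths (2–6 s), pulse heights (0.87–1.0), sharp and smooth edges,
loose and tight solver tolerances, and the two-stage mRNA model (which is
worse: the extra low-pass attenuates the pulse drive below the latch's
commit threshold entirely).

`buffered_wiring=True` interposes one relay Buffer gene per
flip-flop-to-flip-flop J/K link. Its gene-expression delay (one decay time,
1/γ = 1 s) lets the downstream stage read the *pre-edge* value of the
upstream output — precisely the mechanism the carry genes `G_k` already
provide for counter stages ≥ 3. With relays the counters divide exactly:
Q1 at 2× (64.6 s), Q2 at 4× (129.2 s) and the mod-3 output gene at 3×
(96.9 s) the 32.3 s clock period, all full-swing. The default remains direct
wiring, which preserves the canonical structure and species counts
(δ = 2 → 12 species, mod-3 → 18 + 1).

## Numerics

* Integrator: `scipy.integrate.solve_ivp`, LSODA by default (stiff-capable,
  auto-switching); method is a setting and an explicit RK45 run reproduces
  the oscillator metrics to < 0.01 %.
* Tolerances rel 1e-8 / abs 1e-10; halving both changes the oscillator
  metrics by < 1e-6 relative (asserted at < 0.1 %).
* Output grid 0.01 s: ≥ 3200 samples per 32 s cycle, so duty-cycle
  quantization error < 0.1 pp.
* When a circuit has external drives (square-wave clocks for flip-flop unit
  tests), the solver step is capped at 0.5 s so a 3 s pulse cannot be
  stepped over. Drive pulses use tanh edges (0.3 s) — a hard discontinuity
  would defeat adaptive step control.
* Transient removal: all metrics discard the first 30 % of a run (the
  circuits settle within ~3 cycles; 30 % of a 500 s run is conservative).
  Run lengths: 500 s for oscillator/shaper measurements (≈ 10 steady
  cycles), 900 s for counters (≈ 4–6 steady cycles of the divided outputs).
* Peak-based period uses quadratic sub-grid interpolation and a prominence
  filter at half the swing, merging plateau ripple into one peak per cycle;
  for square-wave (latch) outputs, whose maxima sit anywhere on a long flat
  plateau, `period_from_edges` (mean rising-edge spacing with a 5 %
  hysteresis band) is the appropriate estimator and is what the counter
  tests use.
* Negative solver undershoot is clipped to zero in reported traces only.

## Limitations

* Deterministic ODE kinetics only: no stochastic (SSA) simulation, no
  cell-cell coupling, no delay differential equations, no spatial effects.
* The gate model is phenomenological Hill logic; thermodynamic promoter
  models, protease-controlled degradation and parameter inference from
  fluorescence data are out of scope.
* SBML export covers autonomous circuits (rate rules); external drives are
  not exportable and raise an explicit error.
* The shaper designer selects thresholds, not physical parts; mapping a
  design onto a concrete promoter-RBS library is not attempted.
* Synchronous counters beyond the binary 2^δ family and the mod-3 topology
  (general modulus-N synthesis) are not implemented.
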