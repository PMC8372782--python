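# Methods

## Model

An isolated spin-1/2 evolves under a shaped RF pulse, in the rotating
frame, through the SU(2) propagator U = exp(−iγI_z) exp(−iβI_x) exp(−iαI_z).
The package computes the Euler angles (α, β, γ) along two independent
routes:

1. **Exact segment product (the oracle).** The waveform, sampled at K
   uniform nodes over [0, τ_p], is treated as K−1 rectangular segments
   whose amplitude, phase and offset are the averages of the adjacent node
   values. Each segment rotates about its tilted effective field
   ω_e = (ω₁² + Ω²)^½ (tilt θ = atan2(ω₁, Ω)); the time-ordered product of
   the segment matrices is exactly unimodular, and β = 2·atan2(|U₂₁|,
   |U₁₁|), with α ± γ from the arguments of U₁₁ and U₂₁.
2. **HAM series.** The Riccati variable f = tan(β/2)e^{iγ} satisfies
   df/dt = ½ω₊f² + iΩf + ½ω₋; through d ln y/dt = −½ω₋f this becomes a
   linear second-order ODE which HAM solves as y = Σ yₙ. Method 1
   (y₀ = 1) works for arbitrary complex envelopes and time-varying offset
   laws; method 2 (y₀ = cos(δ/2)) and the direct-Riccati route
   (f₀ = tan(δ/2), orders ≤ 3) require amplitude-modulated x-phase pulses
   at fixed offset and produce power series in Ω.

Relaxation during a pulse is handled by a second HAM layer on the Bloch
equations in the transformed variables M̂ = e^{R₂t}M, with generator
Γ(t) built from Ω, ω_x(t), and −(R₂−R₁). The zero order is the
relaxation-free rotation trajectory; the first order corrects only M̂_z by
−c₀[(R₂−R₁)∫M̂_z0 dt′ + (R₁/R₂)(e^{R₂t}−1)M₀]; higher orders follow
M̂ₙ = (1+c₀)M̂ₙ₋₁ + c₀∫ΓM̂ₙ₋₁dt′. For rectangular pulses (constant Γ) the
series resums exactly to
M(t) = e^{−R₂t}[M₀(t) + ∫ e^{−Γ(t−t′)} (0, 0, (R₂−R₁)M_z0(t′) +
e^{R₂t′}R₁M₀) dt′].

## Parameters that matter

| Parameter | Units | Default | Role |
|---|---|---|---|
| c₀ | — | −1 | HAM convergence control; −1 gives the classical iterated series. `C0_TUNED = −0.925` is a quoted working preset that empirically buys 1–2 orders of accuracy for every built-in shape. |
| N (order) | — | 3 | Series truncation. Working orders: 3 (rectangular), 5 (EBURP-2/REBURP), 7 (Q5), 11 (WURST-20), all at c₀ = −1. |
| K (n_points) | — | 1000 | Grid size; discretization error is O((ω_e Δt)²) for both routes. |
| Ω | rad/s | — | Resonance offset added to the stored offset law; user-facing interfaces use Hz (factor 2π at the boundary). |
| R₁, R₂ | 1/s | 0 | Longitudinal/transverse relaxation rates; M₀ is the equilibrium magnetization (default 1). |

The preset c₀ = −0.925 is deliberately a constant, not a derived quantity:
the analytic condition that the first-order on-resonance rectangular
result equal a 90° rotation gives c₀ = −1/(π/4 + π²/32) ≈ −0.9142
(`first_order_c0_for_90deg`), which does not reproduce −0.925; the
selection procedure behind the quoted value is not fully specified, so it
is shipped as a preset and its benefit is verified empirically instead.

## Built-in shapes and their calibrations

Rectangular (25 kHz/10 µs and 250 Hz/1 ms 90° pulses), EBURP-2
(9 kHz/455.2 µs, 90°), REBURP (10 kHz/626.5 µs, 180°), Q5 Gaussian
cascade (9 kHz/504.9 µs, 90°) and WURST-20 (9512 Hz peak, 50 kHz sweep,
440 µs). BURP Fourier coefficients and Q5 Gaussian parameters are
hard-coded from their original publications; by default each
amplitude-modulated shape is rescaled so its on-resonance flip integral
δ(τ_p) = ∫ω dt equals the nominal flip exactly. The published
peak/duration pairs then serve as a consistency check: REBURP reproduces
its printed peak to 0.002 %, EBURP-2 to 1.4 % and Q5 to 6 % — the spread
reflects the 2–3 digit rounding of the published coefficient tables, not a
calibration defect. The WURST sweep is implemented as a quadratic phase,
low-to-high frequency, rate = sweep/τ_p; with the default parameters the
centre adiabaticity factor is Q = ω₁²/(dΩ/dt) = 5.000, which is how those
parameter values were evidently chosen.

These generated fixtures *are* the study conditions; they emulate ideal
spectrometer output (noise-free, perfectly linear amplifier, exact
timing). Real probes add B₁ inhomogeneity, amplifier droop and timing
granularity, so passing tests demonstrate correctness of the mathematics
on ideal waveforms, not robustness to hardware imperfections.

## Numerical choices

* **Quadrature.** Every nested series integral is a cumulative trapezoid
  sum reusing the inner cumulatives — O(K) work per order. Series
  derivatives always come from their analytic integral forms, never from
  numerical differentiation.
* **Envelope cancellation.** f = −(2/ω₋)(Σy′ₙ)/(Σyₙ) is assembled with
  the common envelope factor of the derivatives divided out analytically,
  so zero-amplitude samples (shape nulls, WURST endpoints) are well
  defined.
* **Singularities.** β → π sends f → ∞; samples where |Σyₙ| falls below
  10⁻¹² of its maximum are flagged, and the CLI profile report falls back
  to the oracle at flagged offsets (exit code 3 marks that this happened).
  tan(δ/2)-based routes flag samples with δ ≈ π. The Ω → 0 limit of the
  rectangular closed form is taken analytically (c₀ω₁²t²/8) below
  |Ωτ_p| < 10⁻⁶.
* **Degenerate Euler extraction.** At β = 0 only α+γ is defined (at β = π
  only α−γ); the defined combination is reported with the gauge angle set
  to 0 and the case flagged.
* **α via time reversal.** α is the argument of f(τ_p) for the
  time-reversed pulse (sample order of envelope and offset law reversed,
  no conjugation), recomputed with the same method and order; the
  direct-integral form of α over the f(t) trajectory is available behind a
  flag. The reversal convention is validated against the oracle for the
  asymmetric EBURP-2 shape in the test-suite.
* **Relaxation bookkeeping.** All series algebra stays in M̂ = e^{R₂t}M;
  conversion to M happens at output only. The R₂ → 0 limit of the source
  term, (R₁/R₂)(e^{R₂t}−1) → R₁t, is substituted symbolically. The exact
  resummation evaluates its convolution integral analytically: the source
  is a four-term exponential sum, so each term is an upper-right block of
  an augmented constant-matrix exponential, evaluated at every node from a
  single eigendecomposition (scipy `expm` fallback if the eigenbasis is
  ill-conditioned). This keeps the resummed route free of quadrature error
  and genuinely independent of the trapezoid-based series when the two are
  compared (agreement with the adaptive ODE reference is ~10⁻⁹).
* **ODE reference.** DOP853 at rtol 10⁻⁹/atol 10⁻¹² on the untransformed
  Bloch equations with a linearly interpolated envelope.

## Design choices where the design was open

* **Grid convention.** Waveforms are sampled at K = 1000 nodes; the HAM
  quadrature runs on the nodes and the oracle averages node pairs into
  segment midpoints. The two conventions agree in the continuum limit and
  the high-order series reaches the oracle at the O(Δt²) floor
  (3×10⁻⁵ rad at K = 1000 for the worst case, WURST-20), which is what
  fixed the default.
* **Offset bands.** Profile comparisons use the band out to the first
  rotation null (Ω/ω₁ = √15) for the hard rectangular pulse, ±6 kHz for
  the band-selective shapes (selective band plus transition regions,
  roughly twice the BURP bandwidth ≈ 4.9/τ_p), and ±25 kHz (the swept
  band) for WURST-20. Bands were fixed from the pulses' design bandwidths
  before tuning anything against them.
* **Method-2 weighting.** The higher series terms enter the total with
  the (2+c₀) weight as derived; at c₀ = −1 this reduces to the plain sum,
  which is the regression anchor.
* **Shape files.** One dialect: Bruker-style ASCII, amplitude as percent
  of peak and phase in degrees, comma- or whitespace-separated; `##`
  headers are tolerated, and the writer records peak (Hz) and duration (s)
  in header comments so files round-trip without side metadata.

## Known limitations

* Method 2 and the direct-Riccati route require amplitude-modulated
  x-phase pulses at fixed offset, as derived; method 1 has no such
  restriction.
* The offset power series degrades rapidly beyond Ω/ω₁ ≈ 1 (third order:
  0.05 rad rotation-angle error at the window edge, growing monotonically
  beyond) — it is kept for the closed forms and effective-delay analysis,
  not as a general profile tool.
* Near the centre of an inversion profile (β → π) the extraction of β
  from a truncated series is intrinsically ill-conditioned because the
  series denominator vanishes there; for WURST-20 at order 11, c₀ = −1
  this leaves a residual rotation-angle error of ≈0.055 rad at the sweep
  centre (order 13: 0.003 rad). The working orders quoted above describe
  figure-level agreement, not a uniform error bound.
* The relaxation layer models time-constant R₁/R₂ of an isolated spin:
  no couplings, exchange, radiation damping or multi-spin effects. For
  shaped (time-varying Γ) pulses the series route is validated only
  against the ODE reference, since no closed forms exist there.
* Wall-clock performance of the series versus the oracle is
  hardware-dependent and deliberately untested.
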