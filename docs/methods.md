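# Methods

## Model structure and assumptions

The simulator implements a deterministic compartmental kinetic model of
AMPA-receptor trafficking around a single postsynaptic spine. Receptor
occupancy is tracked in four *saturable* membrane compartments — the
postsynaptic density (PSD, capacity `T_psd = 1`, the normalization unit),
two small perisynaptic staging pools (PeriIN and PeriOut, capacity 0.2
each) and the unanchored surface pool (UA, capacity 0.2) — each exchanging
receptors with a *non-saturable* internal endocytic reservoir (Endo).

Key structural assumptions:

- **Endo is an infinite reservoir.** No differential equation is carried
  for the endosomal pool; its free-receptor concentration is identically 1
  and is absorbed into the Endo→membrane rate constants. This is the only
  reading consistent with constant exchange rates and a non-saturable
  internal compartment.
- **Sparse transition graph.** The only transitions present are
  PeriIN→PSD, PSD→PeriOut, and the bidirectional exchanges
  PeriIN↔Endo, PeriOut↔Endo, UA↔Endo. PSD↔Endo, PSD↔UA and direct
  Peri↔Peri transport are structurally absent (their rate constants are
  zero in the model that reproduces the data).
- **Donor-side saturation.** The two PSD-bound fluxes carry a
  Michaelis–Menten factor `A·km2/(km2 + A)` in the *donor* occupancy
  (PeriIN for the inbound flux, PSD for the outbound flux), with
  half-saturation `km2 = 0.1` (half a peri pool). The factor is bounded by
  `km2`, so a crowded donor cannot exceed the saturation ceiling; the
  acceptor side contributes its free slots `F_c` as a separate factor.
- **Enzyme gating is autonomous.** The kinase and phosphatase variables
  relax to their resting value 1 with first-order rates `k_kin = 1/4` and
  `k_pp = 1/10` per min, independent of occupancies and agonists (the
  induction machinery itself is not neuromodulated here; neuromodulation
  of induction is deliberately outside this model's scope). The source
  terms are pinned to the relaxation rates so that the resting solution is
  exactly 1.
- **Induction is a multiplicative step.** LTP multiplies the kinase
  variable by 1000, LTD the phosphatase by 400, at induction onset only.
  Captions of the underlying simulations force the asymmetric assignment
  (LTP steps the kinase only, LTD the phosphatase only): LTP must deplete
  PeriIN without touching PeriOut, and conversely for LTD.

## Protocol schedule

A scenario is agonist ∈ {none, gs, gq, gs+gq} × induction ∈ {none, ltp,
ltd}. The schedule tiles [0, 50] min into modulation [0, 9], induction
[9, 11] and post [11, 50]. Agonist rate factors act during modulation *and*
induction (the experimental pairing is delivered at the end of the agonist
application) and switch off afterwards; the initial condition is the
resting equilibrium of the baseline dynamics. Phase ends hand their final
state to the next phase; the enzyme step produces the only discontinuity.

## Parameters

All defaults are the published constants (time in minutes, occupancy in
units of the PSD capacity): `k_periin_psd = 0.001`, `k_psd_periout =
0.004` (the outward bias leaves the resting PSD mostly free, occupancy
≈ 0.37), peri↔endo exchange 1/50, UA↔endo 1/20, Gs factors (100, 10, 4.5)
on the three exocytic rates, Gq factors (10, 100, 2) on the three
endocytic rates.

Two observable-side parameters are not fixed by the published model and
are package choices, configurable and covered by sensitivity tests:

- `tau_smooth = 1` min — time constant of the causal exponential kernel
  smoothing the weight. One minute matches the per-minute averaging of
  slice-physiology response data; every qualitative result is verified to
  be unchanged for tau in [0, 2] min.
- `w_ua = 1` — fraction of unanchored receptors contributing to the
  weight. The methods definition of the weight includes the UA pool
  outright; the fraction is exposed because only part of the UA pool is
  near enough to the synapse to contribute in reality.

## Numerical choices

- **Integrator.** `scipy.integrate.solve_ivp` with LSODA (automatic
  stiff/non-stiff switching; the ×1000 kinase step makes induction onset
  stiff), `rtol = 1e-10`, `atol = 1e-12`, restarted at phase boundaries so
  the enzyme jump is never interpolated across. These tolerances keep the
  kinase variable (magnitude up to 1e3) accurate to ~1e-7 absolute,
  verified against a fixed-step RK4 reference at dt = 1e-3 min. Dense
  output on a 0.1-min grid internally; 1-min grid for export, matching the
  per-minute experimental sampling. Occupancies are clipped to
  `[-atol, T_c + atol]` after each phase solve.
- **Resting equilibrium.** Damped Newton (finite-difference Jacobian,
  step-halving line search) on the 4-dimensional occupancy balance with
  the enzymes at 1, initialized at half capacity; residual required below
  1e-9. Fallback: relaxing the dynamics from empty membrane pools. The
  slowest mode of the linearized baseline dynamics has
  λ ≈ 6.8e-5 min⁻¹ (τ ≈ 1.5e4 min — the "hours to equilibrate" regime),
  so the fallback and the long-integration oracle in the tests use a
  1e6-min horizon; shorter horizons (e.g. 1e5 min) still carry ~3e-4
  residual along the slow mode and cannot certify a 1e-6 agreement.
- **Outcome classification.** Mean normalized weight over the final 5 min;
  the no-change band is ±10%, the conventional no-plasticity margin in
  slice physiology. Under the published constants this band cleanly
  separates the neuromodulator-blocked scenarios — which retain ~7%
  residual plasticity because the stepped enzyme decays over ~10–40 min
  while the agonist's occupancy bias relaxes after washout — from
  expressed LTP/LTD (≥ 16% weight change). A 5% band would misclassify
  the blocked scenarios as plasticity; the residual is a genuine property
  of the printed constants, not an integration artifact.
- **Calibration.** Nonlinear least squares (`scipy.optimize.least_squares`,
  trust-region reflective) on log-transformed parameters with box bounds;
  multi-start (default 3 starts, extra starts log-uniform within bounds).
  Model responses inside the fit are integrated at `rtol = 1e-7` — two
  orders below the 5% observation noise — and interpolated onto each
  trace's time grid. A pre-fit sensitivity screen rejects free parameters
  with no numerical leverage on the supplied scenarios (e.g. the LTD gain
  fitted against LTP-only traces) instead of returning an arbitrary
  number.

## Synthetic data

The generator emulates the experimental observable: a synaptic response
sampled once per minute, normalized to the pre-treatment baseline, with
additive i.i.d. Gaussian noise (default SD 5% of baseline, the visual
scatter scale of slice-physiology baselines). It reproduces neither
correlated drift (rundown, temperature), nor heteroscedasticity, nor the
trial-to-trial variability structure of evoked responses; parameter
recovery results therefore demonstrate identifiability under the model's
own noise assumptions, not robustness to real-data systematics.
Recovery experiments default to 5 traces per scenario per fit, LTP and
LTD no-agonist scenarios, and report relative bias, relative RMSE and
median absolute relative error per freed parameter; everything is
deterministic under a single integer seed.

## Known limitations

- No spatial extent, lateral-diffusion kinetics, receptor stochasticity,
  subunit composition, phosphorylation-site bookkeeping or calcium/
  induction-threshold dynamics; the enzyme steps abstract the entire
  induction cascade.
- The default constants are hand-tuned abstractions, not identified
  quantities; they are one explanation of the phenomenology among many,
  and the calibration module accordingly quantifies recoverability on
  synthetic traces rather than claiming unique estimates from real
  recordings.
- Agonist phases follow the printed 9 + 2 min schedule even though the
  emulated experiments applied agonists for 10 min.
- Blocked-plasticity scenarios retain ~7% residual weight change (see
  classification above); the model "prevents" LTP/LTD in the sense of
  strong attenuation, not complete suppression.
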