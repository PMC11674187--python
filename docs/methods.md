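# Methods

`cardioblock` implements the computational chain of an in vitro cardiac
safety assessment for a state-dependent Na+ channel blocker (the worked
default is cenobamate, an antiseizure drug with class-Ib-antiarrhythmic-like
properties): potency estimation from whole-cell patch-clamp screens,
extraction of conformation-specific blocking kinetics under the modulated
receptor hypothesis (MRH), a drug-extended human ventricular cardiomyocyte
model, and a 1D conduction strand. This note documents the models, the
numerical choices and the limits of what the tests demonstrate.

## Dose–response estimation

Fractional block follows the Hill form `f = 1 / (1 + (IC50/C)^nH)` with the
zero-concentration limit 0. The primary estimator is the single-point route
used in screening assays: the mean fractional inhibition at one test
concentration, corrected for rundown by *plain subtraction* of the mean
inhibition in time-matched vehicle controls, inverted through
`IC50 = C ((1-f)/f)^(1/nH)`. No rescaling by `(1 - control)` is applied —
that convention is what makes the shipped worked values reproduce exactly.
Multi-concentration Hill fits (weighted least squares, `lmfit`,
Levenberg–Marquardt) default to a fixed unitary Hill coefficient; a free
coefficient is opt-in. The default cenobamate potency set is
peak I_Na 87.6, late I_Na 46.5, I_CaL 509.75, I_Kr 1869 (the regulatory
value adopted in preference to the in-house single-point 2711.2 µM),
I_Ks 1336.1 µM; C_max = 170 µM; human plasma free fraction 0.4 (opt-in).

## MRH block-kinetics estimation

The kinetic scheme has closed (C), open (O) and inactivated (I) gating
states plus drug-bound open (OB) and inactivated (IB) states; closed
channels bind with negligible affinity. The estimation chain converts
macroscopic time constants into the four rates `k_ob, k_ob⁻¹, k_ib, k_ib⁻¹`:

* **τ_i, τ_r** — monoexponential decay of the current during a standard
  activation step, and the recovery recurrence applied to use-dependent
  block (UDB) peak sequences:
  `τ_r = t_r / [ln(1 − e^(−t_d/τ_i)) − ln(1 − o_n/o_{n−1})]`.
  For memoryless Markov kinetics this recurrence is exact only for the
  *first* pulse pair of a sweep: channels inactivated on earlier pulses also
  recover during later intervals, so later pairs sit near a quasi-stationary
  availability. The estimators therefore pool the first-pair estimate across
  the sweep family (one interval duration per sweep, 5–50 ms); applying the
  recurrence to all pairs is available as an option. Against the Markov
  oracle, pooled τ_r is accurate to < 0.5%.
* **Open rate sum** — with drug, the decay of the open state obeys a 2×2
  linear system (O↔OB with the inactivation sink), so the *sum of the two
  decay eigenvalues* equals `1/τ_i + k_ob[D] + k_ob⁻¹` identically. The
  sweep-set pipeline consequently fits a double exponential to the drug
  decay and uses `1/τ_fast + 1/τ_slow − 1/τ_i`; a single-exponential fit
  mixes the two eigenvalues and can underestimate the rate sum by tens of
  percent. The desk-level operations (`open_rate_sum`, `tau_ob_from_decay`)
  keep the closed forms used with tabulated monoexponential constants.
* **τ_ib** — the inactivated-state analogue treats "inactivated or blocked"
  as one unavailable pool and reads the slow-down of recovery relative to
  control. The derivation assumes blocked-inactivated channels are
  effectively trapped over a recovery interval; it is accurate (≈ +6%
  against the oracle) when `k_ib[D] ≫ k_ib⁻¹` and biased high when unblock
  is fast (more than 2× at `[D]/K_d(I) ≈ 0.36`). Parameter-recovery tests
  therefore run in the trapping-dominant regime, and a separate test pins
  the weak-binding bias so regressions are visible.
* **Rate splits** — each rate sum is split through its dissociation
  constant, `k⁻ = sum/(1 + [D]/K_d)`, with the open-state K_d taken equal to
  the apparent peak-current IC50 and the inactivated-state K_d transferred
  from the lidocaine–Nav1.5 reference ratio `K_d(I)/K_d(O) = 3.1048`. The
  transfer is a modeling assumption, not an estimate; it cannot be checked
  against the oracle and is supplied explicitly in recovery tests.

The shipped decay-constant table reports reciprocal rates at two decimals
computed from the unrounded retained-row means (1/1.068 → 0.94); the
reproduction path follows that convention, giving the rate difference 0.62
ms⁻¹ where unrounded arithmetic gives 0.628.

## Synthetic patch-clamp data

The generator's Markov model lumps the cubed activation gate into a single
C↔O transition (midpoint −45 mV, slope 4 mV, τ 0.15 ms — chosen so
activation is essentially complete at −10 mV and the macroscopic decay
reflects τ_i to < 1%), inactivates O→I at 1/τ_i, and recovers I→C at
1/τ_r gated to hyperpolarized voltages. Defaults τ_i = 2.47 ms,
τ_r = 3.81 ms are the control estimates from the UDB experiments. Within a
constant-voltage segment the occupancy vector is propagated by the exact
matrix exponential, which preserves positivity and normalization to
round-off; ramps re-evaluate the propagator per sample step. Additive
Gaussian noise uses per-sweep substreams split from one master seed, so
extending a recording never reshuffles earlier sweeps. What the generator
does *not* emulate: series-resistance and capacitance artifacts, leak,
closed-state (tonic) drug block, slow inactivation, and rundown. Passing
parameter-recovery tests therefore demonstrates estimator correctness under
the assumed kinetics, not robustness to those instrumental effects.

## Ventricular cell model

The baseline is the O'Hara–Rudy (2011) dynamic model, re-implemented in
full (endo/epi/mid parameter sets) with a `cipa` variant applying the
CiPA-lineage conductance recalibration (I_NaL ×2.661, I_to ×0.95,
I_CaL ×1.007, I_Kr ×1.013, I_Ks ×1.87, I_K1 ×1.698). Drug effects:

* fast I_Na carries a blocked-state occupancy `b` with
  `db/dt = {m³[avail]k_ob + m³[1−avail]k_ib}[D](1−b) −
  {m³[avail]k_ob⁻¹ + m³[1−avail]k_ib⁻¹} b`, where `avail` is the CaMK-
  weighted availability `(1−f_INaP)hj + f_INaP h_p j_p`; the current is
  scaled by `(1−b)`. Because every term carries `m³`, `b` is frozen at
  diastolic potentials; after pacing at 1×C_max the diastolic occupancy
  settles near 0.38.
* late I_Na, I_CaL, I_Kr and I_Ks are scaled statically by
  `1/(1 + [D]/IC50)`. The alternative of driving I_NaL through `b` as well
  was considered and rejected: the late current's potency (46.5 µM) is
  measured as a steady-state pore block and is not identified by the UDB
  kinetics.

Numerics: Rush–Larsen exponential updates for all gating variables
(including `b` and the release fluxes, which share the `x_inf/τ` form),
forward Euler for voltage, concentrations and CaMK, fixed dt = 0.005 ms
(halving dt moves APD90 by < 0.5 ms). The GHK fluxes use their analytic
v→0 limits. APD90 is measured from the maximum-dV/dt take-off to 90%
repolarization from the AP peak toward the *pre-stimulus diastolic
potential* — robust for depolarized hiPSC-CM-like traces, where an absolute
−90 mV reference would fail; this convention is the package's choice, not
asserted as universal. Q_net is the per-cycle trapezoidal integral of
I_NaL + I_CaL + I_Kr + I_Ks + I_K1 + I_to in µC/µF.

The reference configuration (`reproduction_setup`) is the `cipa` variant at
cycle length 2000 ms (the Q_net convention), stimulus −80 µA/µF × 0.5 ms,
300 pre-pacing beats from quiescent initial conditions, two recorded beats
with a < 0.1 ms beat-to-beat APD90 criterion. 300 beats is a runtime/drift
compromise: APD90 still creeps by ~1 ms relative to very long pacing, well
inside the ±2% reproduction band (endo control 304.7 ms, 1×C_max 266.9 ms).
The base (unrecalibrated) variant gives a control APD90 of ~288 ms at the
same cycle length.

Known limitation: the model runs at its native 37 °C formulation while the
potencies were measured at room temperature; transfer of local-anesthetic
affinities across temperature is unresolved in general, so simulated
concentrations should be read as nominal. APD90 shortening is monotone in
concentration only over the therapeutic range (0–1×C_max): above that, hERG
block (IC50 1869 µM) progressively re-lengthens the AP, so high-multiple
APD responses are non-monotone while Q_net remains above control.

## 1D strand

Fifty cells (100 µm each) couple resistively: the current into cell i is
`G_j (V_{i−1} − V_i) + G_j (V_{i+1} − V_i)` with `1 pS/pF × 1 mV = 10⁻³
µA/µF` and sealed ends. Cells are pre-paced to single-cell steady state at
the run's concentration and copied across the strand (coupled pre-pacing is
prohibitively slow and changes little at steady state); the beat is
launched by stimulating the first three cells for 1 ms — a single-cell
stimulus cannot charge a well-coupled strand. Activation is the time of
maximum dV/dt subject to an upstroke criterion (dV/dt ≥ 10 mV/ms and peak
≥ 0 mV) separating capture from electrotonic depolarization; conduction
velocity is the slope of position on activation time over the central 60%
of the strand. The minimum two-pathway reentry circuit length is the
wavelength product `RP × cv_slow` (300 ms × 2 cm/s → 6 mm).

In this implementation the drug-free strand conducts at ~29 cm/s at
G_j = 6000 pS/pF and ~11 cm/s at 1500 pS/pF, blocks at 300 pS/pF under
high drug, and — because of the ~0.38 tonic blocked fraction at 1×C_max —
shows decremental failure at therapeutic concentration even at normal
coupling. The qualitative corner properties (conduction without drug at
physiological coupling; block under combined uncoupling and drug; velocity
monotone in coupling) are the tested claims; absolute velocities from this
discrete chain should not be read as tissue predictions.

## Problem sizes used in the test suite

Directional and refinement checks run at reduced pre-pacing (40–150 beats)
and on a reduced coupling/concentration grid; the reproduction
configuration (300 beats) is used wherever a printed value is compared.
These sizes are the package's defaults for its validation suite and are
stated in the relevant tests.
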