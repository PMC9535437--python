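# Methods

## Model

`renoreg` simulates the maternal circulation at roughly eight weeks of
gestation as a closed loop of 19 lumped compartments joined by 23
resistive connectors. A compartment is an elastic reservoir: its
pressure is `P = E(t) * (V - V0)`, where `E` is the elastance (inverse
compliance, mmHg/L) and `V0` the unstressed volume. A connector is a
volumeless resistance: the flow it carries is `q = (P1 - P2)/R`, and the
four heart valves additionally block any backward flow exactly (infinite
backward resistance, implemented as a hard clip at zero rather than a
large finite resistance, which would only add stiffness). Volume moves
between compartments by `dV/dt = sum(q_in) - sum(q_out)`, which closes
the loop and conserves total blood volume to machine precision.

The four heart chambers carry periodic time-varying elastances
`E(t) = Ed + a(t) * (Ees - Ed)` with a double-Hill activation `a(t)`
(rise and decay time fractions, two Hill exponents, normalised to peak
1). The atrial activation is the same functional form shifted to late
cycle (offset 0.75 of the period) so atrial contraction immediately
precedes ventricular ejection. The waveform parameters live in the
configuration and can be replaced wholesale.

The kidney is a single lumped nephron: descending aorta -> renal artery
(AD_AR) -> afferent arteriole (AR_GL) -> glomerulus, which drains in
parallel through the efferent arteriole (GL_VR) and the filtrate path
(GL_TU -> TU_VR), both re-joining in the renal vein and leaving through
VR_VC. The GL->TU flow is the model's glomerular filtration rate; all
filtrate returns to the venous side (no urine production is modelled).
The uterine circuit (UA -> SA -> PL -> UV) closes the gestational side
of the systemic circulation.

## Renal autoregulation

Both control mechanisms act on a single actuator, the afferent
arteriolar resistance:

    R_AR_GL(t) = R_base + g_MR * dR_MR(t) + g_TGF * dR_TGF(t)

floored at 5% of `R_base` to exclude non-physical values. `R_base` is
the calibrated baseline AR_GL resistance, so both increments are zero at
the operating point.

**Myogenic response.** The sensed input is the windowed maximum
(systolic) renal-artery pressure over look-back lags [delta1, delta2] =
[0.3 s, 1.2 s]; since the window spans more than one beat, the sensed
value is the systolic peak, and an abrupt pressure rise reaches the
sensor after delta1 while a fall persists for delta2. The sensed
pressure maps to a target conductance for the whole renal path:
constant-flow `q0 = 0.018 L/s` below `p0 = 80 mmHg`, a plateau with
fractional slope `k = 0.5` on [p0, p1 = 180 mmHg], saturated above p1 —
always referenced to the instantaneous caval pressure so the
arteriovenous gradient drives the target. Inverting the conductance and
subtracting the fixed post-afferent network (efferent parallel with the
filtrate path, plus the venous outflow) yields the afferent target
`R_T`; `dR_MR` relaxes toward `R_T - R_base` first-order with time
constant tau1 = 4 s when constricting and tau2 = 5.3 s when dilating.
The printed form of the branch condition selects tau1 when the current
resistance exceeds the target, which contradicts tau1's label as the
*constriction* constant; the default follows the physiological reading
(tau1 when the target is above the current resistance) and
`mr_tau_convention: literal` in the config runs the other reading. The
difference is small (4 vs 5.3 s) and only affects transients.

**Tubuloglomerular feedback.** The macula densa senses the GL->TU flow
delayed by delta3 = 18 s (ring buffer at solver resolution,
nearest-sample lookup — the delay is four orders of magnitude above the
step size, so interpolation is pointless). The activation is the sensed
GFR clamped to [th, sa] = [144, 333] ml/min minus the operating point
op = 149 ml/min; th and sa are by construction the uncontrolled model's
GFR at mean arterial pressures of 80 and 180 mmHg, which the test suite
re-derives. `dR_TGF` relaxes toward the activation with tau3 = 15 s
(constriction) / tau4 = 33 s (dilation). TGF acts only on the afferent
arteriole; the efferent resistance is fixed.

**TGF gain units.** The gain is stored as 200 with explicit units
(mmHg*s/L) per (L/min) of GFR deviation. The unit choice matters: in
(mmHg*s/L)/(ml/min) the same number gives a delayed-loop gain of about
6, which a linearised analysis of `tau3 * x' = -x - K * x(t - delta3)`
places far beyond the Hopf boundary (K ~ 2 for these constants) —
the baseline would carry a sustained ~54 s TGF limit cycle, which is not
how the modelled system behaves. In the shipped L/min convention the
default gain is conservative (loop gain ~6e-3): TGF acts in the correct
direction but weakly. `renoreg.tgf.recalibrate_gain` re-fits the gain so
the closed-loop %ΔRBF of a 100->148 mmHg step matches a user-supplied
reference value, which is how the gain is meant to be anchored to
observations; fitting a +20% reference yields a gain near 2.2e4
(mmHg*s/L)/(L/min), i.e. ~22 per ml/min — comfortably inside the
stability region.

## Numerical scheme

Explicit Euler at dt = 1 ms (configurable). The controller updates are
themselves written as per-step discrete relaxations, so a fixed-step
explicit scheme integrates model and controllers in lockstep; the
controller writes the new afferent resistance for the *next* step (an
explicit one-step lag, error O(dt)). The stiffest time constants
(aortic valve into the ascending aorta, ~2.7 ms) keep dt/tau below the
Euler stability bound of 2 with margin. The cycle period is snapped to
an integer number of steps (870 steps at 69 bpm), so beats align with
the grid and beat-averages are exact integer-cycle means. Volume
conservation is exact up to rounding (each flow enters the balance once
with each sign); 60 s of simulation drifts total volume by ~1e-13 L.

Steady state is declared when every beat-averaged pressure and flow
changes by less than 0.1% (relative, with 1 mmHg / 0.1 ml/s floors)
over three consecutive beats; calibration uses a much tighter 2e-3%
because parameter solves must not chase transients. Pressure-step
protocols instead integrate a fixed hold per level (default 120 s) and
flag convergence by comparing the first and last recorded beats —
deterministic runtimes and an honest flag when a hold is too short.

## Parameter provenance and calibration

The individual elastances, volumes and resistances are not copied from
any table; they are regenerated from their defining targets, in two
layers.

`design_baseline()` lays out a starting point in closed form from design
mean pressures and branch flows (CO 5.8 L/min split 2.2/2.5/1.0/0.1
L/min over upper body, lower body, kidney and uterus; caval pressure
near 4 mmHg; glomerular pressure near 54 mmHg; filtration fraction
0.149). The renal split uses one non-obvious constraint: the
post-afferent lumped resistance is pinned by the maximal-dilation
anchor. With the myogenic curve fixed (q0, k, p0, p1), requiring the
afferent target resistance at a sensed pressure of 180 mmHg to sit
exactly 20% below the maximally dilated (80 mmHg) radius via
`R ~ r^-4` determines the downstream resistance in closed form:

    R_down = (cinv(p1) - rho * cinv(p0)) / (1 - rho),   rho = 0.8^-4

with `cinv(p)` the inverse target conductance. The remaining drop is
distributed over the individual renal connectors by the design pressure
profile.

`GestationalCirculation.fit()` then calibrates, in stages, against the
simulated model itself:

1. **Systemic** — a nested solve: for each joint scale of the four
   body-bed resistances (AA_UB, AD_LB, UB_VC, LB_VC) the stressed
   volume (through the caval compartment) is first re-solved so MAP
   sits at 82.5 mmHg, then the cardiac output at that pressure is
   compared with 5.8 L/min. Nesting matters: in a closed loop CO is
   venous-return-limited, and at fixed volume it responds only weakly
   (and not even monotonically) to the arterial bed resistances alone.
2. **Renal** — the split is re-derived from the *measured* aortic and
   caval pressures (keeping the design's intra-renal offsets), all six
   renal resistances are scaled jointly until the AD->AR flow is
   1.0 L/min, then GL_TU alone is trimmed until the GL->TU flow is
   0.149 L/min. The re-derivation is skipped when it would move
   resistances by <0.3%, keeping calibration idempotent.
3. **Operating-point quiescence** — the renal-artery compartment
   elastance is solved so that the myogenic target resistance at the
   sensed (systolic) AR pressure equals the calibrated afferent
   resistance. The AR elastance only shapes the pulse transmitted into
   the kidney, not the mean flows, so it is the one free knob that can
   zero `dR_MR` at baseline without disturbing the other targets. This
   is why the closed-loop model with both controllers active sits still
   at its calibrated operating point (afferent resistance within 1% of
   `R_base`, GFR at the TGF operating point).

Stages repeat once (`refine=1`); the converged volume distribution is
frozen into the calibrated config so fresh runs start at periodic steady
state. All solves are damped secant iterations with analytic starting
brackets; each function evaluation is a steady-state run warm-started
from the previous converged volumes. MAP is an explicit target because
the TGF band edges (144/333 ml/min) are only consistent with the GFR
operating point if the baseline perfusion gradient is right; 82.5 mmHg
is a representative early-first-trimester value and makes the three
renal targets mutually consistent.

## Protocols

The **renal perfusion clamp** replaces the renal-artery compartment by a
prescribed pulsatile pressure source (systolic = protocol level, pulse
pressure 40% of systolic, a sin^2 systolic hump over 2/3 of the cycle so
the mean is diastolic + PP/3) and holds the caval outlet at its baseline
mean pressure; GL, TU, VR and both controllers run dynamically. This
mirrors the isolated-nephron preparations the controllers are validated
against and decouples renal validation from systemic calibration.
Controller state persists across levels, as in the source experiments.
The **whole-body** variant loads the closed loop with stressed volume
until MAP reaches each level (used for the TGF band-edge derivation);
under heavy loading the caval pressure rises (to ~13 mmHg at MAP 180),
which is why the uncontrolled GFR at 180 mmHg lands ~2% below the
nominal saturation value.

Reported quantities per level: beat-averaged RBF, GFR, afferent
resistance (per-step controller output averaged over the recording
window), renal vascular resistance (mean AR-VC gradient over RBF;
afferent-only change is also emitted), and percent changes versus the
first level, with radius changes via the inverse-fourth-power relation.
The deviation scorer grades |model - reference| in percentage points
into the bands <10 very good, 10-20 good, 20-30 fair, >30 poor.
Sensitivity analysis re-runs a protocol with k or the TGF gain scaled by
±10/±20% and reports the largest change in any percent-change output.

## What the defaults do and do not show

The shipped configuration reproduces the *calibrated operating point*
and the *controller behaviour around it*: flows, pressures and percent
responses to pressure steps in 80-180 mmHg. It is not fitted to any
individual's data; the systemic beds are coarse two-resistance lumps,
there is no baroreflex, renin-angiotensin system, blood composition or
colloid-osmotic physiology, and glomerular filtration is purely
pressure-driven (the GL_TU resistance absorbs the osmotic terms). Animal
reference observations are deliberately not bundled: the deviation
scorer takes user-supplied reference values.

## Numerical and design choices, briefly

- dt = 1 ms; halving dt changes beat-averaged outputs well below the
  calibration tolerance because targets are calibrated post-
  discretisation.
- Warm-up: controller delay buffers are pre-filled with the initial
  sensed values, so controllers are quiescent at t = 0 and delayed
  responses are measured from signal deviation, not from start-up.
- Negative transmural pressures are allowed (no collapse model).
- Protocol holds default to 120 s; with TGF active the slow dilation
  tail (tau4 = 33 s) is not fully settled at that hold — residuals are
  ~1e-3 percentage points, noted by the convergence flag machinery
  rather than hidden by longer defaults.
- Problem sizes in the test-suite and the acceptance script (hold
  durations, beat windows, solver tolerances) are chosen as the smallest
  that leave measurement residuals an order of magnitude below the
  assertion tolerances.
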