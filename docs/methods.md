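# Methods

`cardioem` is a desk-scale, fully 0D/1D re-expression of a multiscale
cardiac electromechanics study: how systolic heart failure (HF) and a
continuous-flow left ventricular assist device (LVAD) reshape left- and
right-ventricular hemodynamics. This note records the models, their
assumptions, the numerical choices, and what the package's tests do and do
not establish.

## Model chain

1. **Calcium transient** (`calcium`). One beat of cytosolic calcium is
   either generated analytically or extracted from the ionic model. The
   analytic form is a normalized bi-exponential,
   `Ca(t) = ca_dia + ca_amp * (e^(-t/tau_d) - e^(-t/tau_r)) / M`, with `M`
   chosen so the absolute peak is exactly `ca_dia + ca_amp`. Defaults
   (0.1 µM diastole, 0.9 µM amplitude, 20/150 ms rise/decay, 800 ms cycle)
   resemble a paced human ventricular myocyte. HF is imposed by scaling the
   amplitude to 70% and the *decay* time constant to 70% of normal —
   "magnitude" is read as peak-above-diastole and "time constant" as the
   decay constant, the dominant time scale of a calcium twitch. (Failing
   human myocytes usually show *slowed* decay; the faster-decay direction
   is retained here as the study condition being reproduced.) Diastolic
   calcium and rise kinetics are left untouched by the remodeling.

2. **Ionic model** (`ionic`). The 2004 ten Tusscher–Noble–Noble–Panfilov
   human ventricular equation set, epicardial variant by default (the
   variant and cell type are a documented package choice; all constants are
   transcribed from the 2004 publication). Concentrations and voltage
   advance by forward Euler at dt = 0.01 ms; gates use Rush–Larsen
   exponential updates, which are exact for the locally linear gate ODEs
   and preserve [0, 1]. The calcium-dependent gates (f_Ca and the release
   gate g) freeze while depolarized above −60 mV, as published. The default
   stimulus is −52 pA/pF for 1 ms (a conventional suprathreshold choice;
   negative = depolarizing in this sign convention). A dedicated test
   compares every current formula against a second, independently written
   transcription.

3. **Monodomain cable** (`cable`). The monodomain reaction–diffusion
   equation on a 1D fiber with second-order central differences, no-flux
   ends, and the ionic model as the reaction term. Units (mS/cm, 1/cm,
   µF/cm², cm, ms, mV) are mutually consistent with no hidden conversion
   factor. Defaults: 100 nodes, dx = 0.01 cm, β = 1400 cm⁻¹, C_m = 1 µF/cm²,
   σ = 1.75 mS/cm, giving a conduction velocity (CV) of ≈66 cm/s; a
   "Purkinje-like" preset scales σ by (200/66)² to hit the clinical
   200 cm/s (a calibration, not a measured conductivity). The explicit
   stability bound dt < C_m·β·dx²/(2σ) is checked before stepping. CV is
   the least-squares slope of distance on activation time over the central
   half of the cable. The 1D geometry stands in for a 3D ventricular solve;
   the governing PDE is the same, the geometry is not.

4. **Myofilament** (`myofilament`). The Rice et al. (2008) approximate
   cross-bridge model: calcium binds low/high-affinity troponin; a steep
   permissivity switch (perm50 = 0.5, n = 15) gates the nonpermissive →
   permissive transition; permissive units attach (f_app), rotate
   (h_f/h_b), and detach consuming ATP (g_xb); mean distortions of the two
   attached states evolve with their own ODEs and weight the tension sum;
   thick/thin-filament overlap modulates recruitment with sarcomere length.
   Published baseline rates are used without temperature rescaling. The
   tension scale (120 kPa at full activation and overlap) and the strain
   modulation cap (×20, a numerical guard against explicit-integration
   stiffness during rapid shortening) are package parameters.

   Loading uses an afterloaded force balance: the muscle holds its initial
   length until active + passive tension exceeds the load, then shortens
   quasi-statically through a small viscous term (50 kPa·ms/µm, fast
   relative to twitch time scales); passive tension is a titin-like
   symmetric exponential about a 1.9 µm slack length. A 1000 kPa load can
   never be reached, so the high-load protocol *is* the isometric protocol;
   a hard length clamp is provided as an alternative and agrees to <1%.
   The single-cell passive/loading arrangement is a package design choice —
   the study being reproduced does not state one.

   Each twitch runs 10 beats driven by the periodic transient and reports
   the last beat. ATP consumption is the overlap-weighted detachment flux
   g_xb·XBpostR, normalized by the normal-isometric peak for display.

5. **Circulation + LVAD** (`circulation`). A closed 8-compartment loop
   (LA, LV, RA, RV, systemic artery/vein, pulmonary artery/vein). Vessels
   and atria are passive stressed-volume compliances (P = V/C); there is no
   atrial kick. Valves are ideal diodes smoothed by a 0.01 mmHg softplus so
   the vector field stays smooth; no inertance, no regurgitation. The
   ventricles are 0D surrogates blending an end-systolic elastance line
   with an exponential end-diastolic relation,

       P(V, a) = a_eff·E_es·(V − V0) + (1 − a_eff)·A·(e^{B(V−V0)} − 1),

   driven by the activation a(t): the isometric myofilament tension under
   the condition's calcium transient, normalized by a per-ventricle
   reference tension and clipped to [0, 1]. The normalized activation is
   sharpened by a cooperative exponent, `a_eff = a^2`, before blending:
   chamber pressure generation falls off faster than myofilament tension
   when activation is submaximal, standing in for the length- and
   geometry-dependent losses of a deforming ventricle. Without this
   sharpening the unloaded failing LV retains enough pressure to keep
   opening the aortic valve, and the pump cannot abolish the isovolumetric
   phases. The RV reference tension is set low enough that normal RV
   activation saturates (clips at 1): the RV then loses proportionally less
   contractility in HF than the LV, which is what lets right-sided
   congestion rather than RV weakness dominate the HF response.

   The LVAD is a pure flow source (4 L/min default) from LV to systemic
   artery, time-independent, with one safeguard: the set flow tapers
   smoothly when LV volume falls below ~12 mL, so the flow generator cannot
   draw the chamber negative (a suction limit; it does not engage at
   steady state under the default conditions).

   Integration is fixed-step RK4 at dt = 0.25 ms. A fixed-step scheme was
   chosen over an adaptive stiff solver deliberately: with the smoothed
   diodes the system is non-stiff at this dt, and fixed stepping makes runs
   bitwise reproducible. Because every flow appears once as a source and
   once as a sink, total blood volume is conserved to round-off, pump on or
   off. Scenarios run 25 cycles at BCL 800 ms; steady state is verified
   (last-two-beat LV EDV change < 1%), not assumed, and a warning is issued
   otherwise.

6. **Passive material** (`material`). The Fung-type exponential strain
   energy W = (C/2)(e^Q − 1) with
   Q = b1·E_ff² + b2·(E_rr² + E_cc² + 2E_rc²) + 2b3·(E_fr² + E_fc²),
   C = 2 kPa, b1 = 8, b2 = 2, b3 = 4 (fiber / transverse / fiber-shear
   semantics). The second Piola–Kirchhoff stress is the analytic gradient,
   verified against central finite differences. Evaluation is at material
   points only; no volumetric penalty is added (near-incompressibility is a
   continuum-level concern outside this scope).

7. **Hemodynamics** (`hemodynamics`). From one steady-state beat: EDV/ESV
   are the volume extremes, EDP the pressure at the EDV sample, ESP the
   beat's peak pressure (a "pressure at ESV" mode exists behind a flag),
   SV/EF/CO by the standard identities with heart rate 60000/BCL, and
   stroke work |∮P dV| by the shoelace rule on the closed loop. Negative
   EDP is legal (below atmospheric). Percent changes are signed,
   100·(new − baseline)/baseline, displayed rounded to integers. Valve
   opening duration is the time a valve's flow exceeds 10% of its beat
   peak. Isovolumetric phases are intervals with |dV/dt| < 0.5 mL per
   10 ms sustained ≥ 20 ms while pressure swings > 5 mmHg; the threshold
   sits deliberately *below* the 0.67 mL/10 ms drain rate of a 4 L/min
   pump, so a pump-drained (slanted) PV segment does not count as
   isovolumetric while a true both-valves-closed plateau does.

## Calibration

The circulation has no published parameter values. `calibrate_normal`
fits free parameters by bounded least squares against normal-condition
hemodynamic targets (LVESP 110 mmHg, LVEDV 112 mL, CO 3.8 L/min, RVESP
16 mmHg, and companions); the shipped defaults in
`src/cardioem/params/circulation_normal.json` were produced by this
calibration plus a directional screen across all three conditions, then
frozen. Absolute reproduction of the reference 3D model's full table is
explicitly **not** claimed — the 0D surrogate is held to (a) the normal
condition's headline windows (LVEF within ±5 points of 46%, CO within
±15% of 3.8 L/min) and (b) the signed directions of every HF and LVAD
effect.

One directional caveat survives calibration: with passive atria and a
flow-source pump in a strictly volume-conserving loop, the RV must pass
the pump flow plus any residual LV output, so RV throughput under LVAD
*exceeds* the HF value by construction. The package reproduces the
right-sided *pressure* unloading and output/EF/SV gains; the magnitude of
the stroke-work drop is smaller than in the reference study, whose
coupled 3D model reports an RV output below the pump's set flow —
impossible in a closed conservative loop — indicating their coupling does
not conserve volume per cycle the way this one does.

A further documented discrepancy inside the reference study itself: its
headline summary reports the RV end-systolic pressure falling "by 53%"
under LVAD, while its own tabulated pair (19 → 7 mmHg) gives −63%. The
package computes from the tabulated values and treats them as canonical
(likewise RVEDV 136 mL over the running text's 137 mL).

## What the synthetic data do and do not show

The synthetic PV fixtures (`synth_pv_fixture`) are smooth four-phase loops
hitting prescribed ESP/EDP/EDV/ESV exactly, with optional seeded noise.
They exercise the summarizer's arithmetic (round trips are exact by
construction) but contain no valve dynamics, no measurement noise
structure, and no beat-to-beat variability; passing them shows the
summarizer is correct, not that it is robust to clinical pressure traces.
Similarly, the analytic calcium transient reproduces the *shape and
scaling* of the study's transients, not stochastic release or alternans;
and the 1D cable demonstrates the monodomain physics, not ventricular
activation geometry.

## Numerical summary

| quantity | value | rationale |
|---|---|---|
| ionic dt | 0.01 ms | published protocol; halving changes Ca peak < 1% |
| cable dt / dx | 0.01 ms / 0.01 cm | stability bound checked; CV dt-converged < 2% |
| myofilament dt | 0.02 ms (twitch), ≤ 0.1 ms (API cap) | explicit scheme vs. 2 ms⁻¹ rates |
| circulation dt | 0.25 ms RK4 | smooth diodes; volume conserved to round-off |
| diode smoothing | 0.01 mmHg | below any hemodynamic scale of interest |
| cell cycles / system cycles | 10 / 25 | last beat reported; steady state verified |
| steady-state bounds | < 1% EDV change | warning, not error, if exceeded |

## Known limitations

- One representative calcium transient per condition (no spatial
  heterogeneity); one activation waveform for both ventricles, scaled per
  ventricle by its reference tension.
- No septal interaction, pericardium, baroreflex, coronary flow, atrial
  contraction, valve inertance or regurgitation; the pump has no
  pressure-head curve (pure flow source).
- The ventricle surrogate's cooperative exponent and reference tensions
  are calibration devices, not measured quantities; absolute pressures
  and volumes outside the normal-condition targets are not claimed.
- Total blood volume is fixed; the renal volume retention that raises
  venous pressures in clinical HF is absent, so right-atrial congestion
  under HF is reproduced in direction but is modest in magnitude.
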