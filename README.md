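# cardioem

Desk-scale cardiac electromechanics for studying how systolic heart
failure (HF) and a continuous-flow left ventricular assist device (LVAD)
reshape left- *and* right-ventricular hemodynamics.

The package chains four levels of cardiac physiology:

1. **Excitation** — the 2004 ten Tusscher human ventricular ionic model
   (single cell, plus a 1D monodomain cable for conduction), or an
   analytic calcium transient standing in for it;
2. **Contraction** — a Rice-type cross-bridge model turning calcium into
   active tension, muscle shortening and ATP consumption;
3. **Circulation** — tension-driven 0D ventricles in a closed lumped
   cardiovascular loop with diode valves and an optional constant-flow
   LVAD (4 L/min from LV apex to aorta);
4. **Analysis** — pressure–volume loop summaries (ESP, EDP, PP, EDV, ESV,
   SV, EF = 100·SV/EDV, CO = SV·HR, SW = |∮P dV|) and percent-change
   comparisons between conditions.

Heart failure is modeled as calcium-transient remodeling: peak amplitude
reduced to 70% of normal and the decay time constant shortened by 30%.
Three conditions are simulated — `normal`, `hf`, and `hf_lvad` — each for
25 cycles at a basic cycle length of 800 ms, and the last steady-state
beat is analyzed.

Intended users: cardiovascular modelers and students who want a fully
inspectable, laptop-scale electromechanics pipeline rather than a 3D
finite-element stack.

## Worked example

```python
from cardioem import run_scenario, summarize_beat, percent_change

runs = {c: run_scenario(c, n_cycles=25) for c in ("normal", "hf", "hf_lvad")}
summ = {c: summarize_beat(r.last_beat(), 800.0) for c, r in runs.items()}

n, h, l = summ["normal"], summ["hf"], summ["hf_lvad"]
print(f"normal : LVESP {n.lv.esp:5.1f} mmHg  LVEF {n.lv.ef:4.1f}%  CO {n.lv.co:.2f} L/min")
print(f"hf     : LVESP {h.lv.esp:5.1f} mmHg  LVEF {h.lv.ef:4.1f}%  CO {h.lv.co:.2f} L/min")
print(f"hf_lvad: LVESP {l.lv.esp:5.1f} mmHg  LVEF {l.lv.ef:4.1f}%  CO {l.lv.co:.2f} L/min")
print(f"LVAD effect on RV: ESP {percent_change(h.rv.esp, l.rv.esp):+.0f}%, "
      f"EF {percent_change(h.rv.ef, l.rv.ef):+.0f}%")
```

prints

```
normal : LVESP 134.4 mmHg  LVEF 44.4%  CO 3.54 L/min
hf     : LVESP  85.8 mmHg  LVEF 25.0%  CO 2.30 L/min
hf_lvad: LVESP  34.1 mmHg  LVEF 33.4%  CO 1.55 L/min
LVAD effect on RV: ESP -23%, EF +31%
```

Reading: heart failure depresses left-ventricular pressure generation and
output while congesting the right side; switching the pump on unloads both
ventricles — right-sided pressures fall while right-ventricular ejection
fraction recovers. The calibrated normal condition reproduces the headline
physiology (ejection fraction near 46%, cardiac output near 3.8 L/min);
the HF and LVAD rows are validated by their signed directions, not their
absolute values (see `docs/methods.md`).

The same experiment is available from the shell:

```bash
cardioem experiment --out results/   # all three conditions + comparison table
cardioem twitch --mode isotonic --load-kpa 10   # single-cell shortening protocol
cardioem cable                                  # 1D conduction demo
cardioem material --strain-json '{"e_ff": 0.1}' # passive stress at a point
```

## Layout

| module | contents |
|---|---|
| `cardioem.calcium` | calcium transients, HF remodeling, normalization |
| `cardioem.ionic` | ten Tusscher 2004 single cell (numba-accelerated) |
| `cardioem.cable` | 1D monodomain fiber, activation times, conduction velocity |
| `cardioem.myofilament` | Rice-type cross-bridge model, twitch protocols, ATP |
| `cardioem.material` | Fung-type exponential passive law and its stress |
| `cardioem.circulation` | closed-loop lumped model, LVAD, calibration |
| `cardioem.hemodynamics` | PV-loop summaries, percent changes, synthetic fixtures |
| `cardioem.pipeline` / `cardioem.cli` | the three-condition experiment and its CLI |

Model equations, assumptions, calibration provenance and known
limitations are documented in `docs/methods.md`.
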