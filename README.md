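# kvflux

Quantitative analysis of arterial-myocyte voltage-gated K⁺ (KV) currents and
cerebrovascular readouts, built for studies of cerebral small-vessel
function: how many functional KV channels does a cerebral-artery smooth
muscle cell carry, and how do myogenic tone and cerebral blood flow (CBF)
respond when that number changes?

## Who it is for

Electrophysiologists and vascular physiologists analyzing:

* whole-cell voltage-clamp **current families** from isolated arterial
  myocytes (10-mV steps, tail currents at a fixed repolarization voltage);
* **pressure-myography** sessions (active vs Ca²⁺-free passive diameter);
* **laser-Doppler flowmetry** traces of functional hyperemia;
* **evoked field potentials** (N1 amplitude) from the somatosensory cortex.

A seeded synthetic-data generator produces all of these inputs with known
ground truth, so every stage of the pipeline is testable end to end.

## The core calculation

The number of functional channels per cell is estimated from macroscopic
current with the Goldman–Hodgkin–Katz (GHK) constant-field framework:

1. **Permeability from conductance.** With single-channel conductance γ
   measured in symmetric [K⁺]:

       P_K = γ / [K⁺] · RT / F²

   ([K⁺] in mol/cm³; γ = 15 pS in 140 mM K⁺ at 23 °C gives
   P_K = 2.83 × 10⁻¹⁴ cm³/s).

2. **Single-channel current from GHK flux.** At membrane potential *V*
   under the physiological gradient (3 mM out / 140 mM in), with
   u = zVF/RT and outward flux positive:

       i = P_K · F · u/(1 − e⁻ᵘ) · ([K⁺]ᵢ − [K⁺]ₒ e⁻ᵘ)

   (≈ 0.14 pA outward at −40 mV).

3. **Channel number from the macroscopic amplitude.**

       I = i · N · P_o   ⟹   N = I / (i · P_o)

   with P_o the open probability at the same voltage (0.014 at −40 mV).
   The macroscopic I is the steady-state current at the tail voltage,
   extracted as the offset of a mono-exponential fit to each sweep's tail.

Around this chain the package provides standard voltage-clamp analysis —
current density (pA/pF) at the end of the pulse, Boltzmann fits
I = I_max / (1 + e^((V₀.₅−V)/k)) to normalized tail peaks, and
mono-exponential activation/deactivation time constants — plus the vascular
formulas: myogenic tone = (passive − active)/passive × 100 per pressure,
percent CBF response = 100 × (CBF_stim − CBF_rest)/CBF_rest after
biological-zero correction, and N1 amplitude within a post-stimulus window.

## Worked example

```python
import kvflux as kf
from kvflux.units import PS

env  = kf.PhysEnv.from_celsius(23.0)
cond = kf.IonConditions.from_mm(3.0, 140.0)

pk  = kf.permeability_from_conductance(15.0 * PS, 140e-6, env)
i40 = kf.ghk_single_channel_current(pk, -0.040, cond, env)
print(f"P_K  = {pk:.3g} cm^3/s")
print(f"i(-40 mV) = {i40 / 1e-12:.3f} pA")

fam = kf.simulate_current_family(kf.SimScenario(seed=1))   # 3120 channels
res = kf.analyze_family(fam, {"count": {}})
print(f"V0.5 = {res.boltzmann.v_half:.1f} mV, k = {res.boltzmann.slope_k:.1f} mV")
print(f"density at +60 mV = {res.iv.iloc[-1]['density_pA_per_pF']:.1f} pA/pF")
print(f"N = {res.count.n_rounded} channels (true 3120)")
```

prints

```
P_K  = 2.83e-14 cm^3/s
i(-40 mV) = 0.142 pA
V0.5 = -11.9 mV, k = 7.2 mV
density at +60 mV = 160.7 pA/pF
N = 3120 channels (true 3120)
```

P_K and i are the two fixed links of the counting chain; V₀.₅/k confirm the
fitted activation curve matches the simulated gating (−12 mV / 7 mV); the
recovered N matches the 3120 channels the simulator put in the cell.

The same pipeline runs from the shell on CSV/JSON inputs:

```bash
kvflux simulate --kind vclamp --seed 1 --out sim/
kvflux count-channels --sweeps sim/sweeps.csv --descriptor sim/descriptor.json \
       --out counts.json
kvflux myotone --input pressure.csv --out tone.json
kvflux cbf --trace ldf.csv --events ldf_events.json --out cbf.json
```

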