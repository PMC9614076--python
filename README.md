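# uwbmotion

Noncontact quantification and lateralization of infant limb movement from
two bilateral impulse-radio ultrawideband (IR-UWB) radar sensors, with
agreement statistics against actigraphy and video tracking.

## The problem

Asymmetric spontaneous movement in early infancy can be an early sign of
unilateral motor impairment, but conventional assessment is observational
and hard to quantify, and contact sensors are impractical on fragile
newborns. Two IR-UWB radars placed on either side of a cradle record, 20
times per second, the reflected amplitude `y_i,n[k]` at each fast-time
range bin `k` (distance from radar `i`), giving a noncontact, side-resolved
measurement of how much the infant moves.

## The method

For each radar the pipeline:

1. **Preprocesses** the frame matrix: zero-phase Butterworth bandpass along
   slow time (default 0.1–9 Hz) and clutter removal by background
   subtraction (per-bin temporal mean, or an exponential running
   background).
2. **Localizes the body center**: the bin `L_signal` with maximal
   respiratory-band (0.3–1.2 Hz) Welch power — respiration is always
   present and strongest at the abdomen/chest, so that bin marks the body
   center and bounds the bins attributable to this radar's side.
3. **Quantifies movement** per frame:

   ```
   E_i[n] = Σ_{k=0}^{L_signal} g_i,n[k],
   g_i,n[k] = |y_i,n[k] − y_i,n−1[k]|  if y_i,n[k] > T_i[k], else 0
   ```

   where `T_i[k]` is a per-bin noise threshold estimated from a
   movement-free calibration window. The 20 values per second are
   averaged to a 1 Hz series, and seconds with caregiver interference are
   marked missing.
4. **Lateralizes**: `Lt/Total (%) = 100 · ΣE_left / (ΣE_left + ΣE_right)`
   over jointly valid seconds (and `Rt/Total` symmetrically) — the
   asymmetry index.
5. **Validates** against reference modalities — 1 Hz actigraphy
   (accelerometer vector-magnitude counts) and CAMSHIFT video tracking of
   limb displacement — using Lin's concordance correlation coefficient
   `ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with Fisher-z 95% confidence
   intervals.

Because no recordings are distributable, the package includes a phantom
generator: one latent movement scenario drives synthetic radar frames,
actigraphy counts and video blobs simultaneously, so every stage can be
tested for ground-truth recovery.

## Worked example

```python
from uwbmotion import make_session_scenario, run_pipeline

scenario = make_session_scenario(seed=1)   # 60 s, latent left:right = 3:1
report = run_pipeline({"scenario": scenario, "session_id": "demo"},
                      outdir="out/demo")
print(open("out/demo/report.txt").read())
```

prints

```
Session: demo
Seed: 1

Body-center localization (L_signal):
   left: bin 40 (confidence 1.000)
  right: bin 40 (confidence 1.000)

Movement lateralization:
  Lt/Total: 74.9 %
  Rt/Total: 25.1 %
  seconds used: 60

Agreement (CCC with 95% CI):
  Actigraphy vs Video      left  rho_z=0.9563 [0.9273, 0.9739] n=59
  Actigraphy vs Video      right rho_z=0.9681 [0.9468, 0.9810] n=59
  IR-UWB vs Actigraphy     left  rho_z=0.9380 [0.8979, 0.9626] n=60
  IR-UWB vs Actigraphy     right rho_z=0.9132 [0.8583, 0.9474] n=60
  IR-UWB vs Video          left  rho_z=0.9450 [0.9089, 0.9671] n=59
  IR-UWB vs Video          right rho_z=0.9218 [0.8713, 0.9529] n=59
```

Both radars recover the phantom's body-center bin (40) exactly; the
session's latent 3:1 left:right movement-energy ratio appears as
Lt/Total ≈ 75%; and the radar-derived per-second series agrees strongly
with the actigraphy and video series driven by the same latent events.

The same steps are available as a CLI (`uwbmotion simulate / preprocess /
localize / quantify / asym / agree / run`) for file-based workflows.

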