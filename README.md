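# ocipipe

Quantification pipeline for multi-channel **optical cochlear implant (oCI)**
electrophysiology. Optogenetic stimulation of spiral ganglion neurons
promises more spectrally selective hearing restoration than electrical
implants, because light can be confined in the cochlea where electrical
current spreads. Testing that claim requires a quantitative chain from raw
midbrain recordings to statements like *"a block of four μLEDs excites
1.8 octaves of the tonotopic axis at d′ = 2"*. `ocipipe` implements that
chain for 32-channel inferior colliculus (ICC) recordings during μLED,
optical-fiber and acoustic stimulation, together with a seeded synthetic
generator that stands in for the in vivo recordings.

## What it computes

- **Multi-unit spike extraction** — 0.6–6 kHz zero-phase Butterworth
  filtering, threshold at median + 3 MAD, 1 ms artificial refractory
  period; PSTHs (0.25 ms bins) and response-window detection
  (baseline mean + 3 SD criterion); evoked-potential averaging.
- **Cumulative d′ spatial tuning curves (STCs)** — window spike counts
  (3–20 ms after the pulse) per (electrode × intensity), cumulative
  discrimination index over the intensity ladder

  `Δd′_i = (μ_i − μ_{i−1}) / √((σ_i² + σ_{i−1}²)/2)`, starting at the
  zero-intensity baseline, so d′ = 1 means a one-pooled-SD rise in firing.
  Per-electrode activation thresholds (interpolated d′ = 1 crossing), best
  electrode (BE), active-electrode counts, iso-contours.
- **Spread of excitation (SoE)** — the electrode span with d′ ≥ 1 at the
  intensity where the BE reaches a criterion d′ ∈ {1.5, 2, 2.5, 3}, with
  sub-threshold gaps bridged by the outermost-electrode rule; converted to
  octaves through each animal's tonotopic slope.
- **Tonotopic calibration** — frequency response areas from pure-tone
  grids, characteristic frequencies, per-animal linear fits of log2(CF)
  against recording depth (octaves/mm), cohort median ± MAD; deaf animals
  receive the hearing-cohort median.
- **Place-code analysis** — BE shift per mm of stimulus location along the
  cochlea, after normalizing every implant to its apical-most responsive
  emitter.
- **Synthetic cohorts** — seeded, statistically structured stand-ins for
  every input: V-shaped acoustic tuning on a 4.34 oct/mm ICC gradient,
  saturating μLED flux curves, Gaussian light spread, sigmoidal SGN
  recruitment over a patchy opsin-transduction profile, Poisson spiking,
  deafened and non-injected control conditions, and raw traces with known
  ground truth. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate one block-of-four μLED run on a fully transduced cochlea and
quantify it:

```python
from ocipipe import (
    ActivationModel, CochlearModel, EmitterLayout, RecordingGeometry,
    ResponseWindow, build_response_matrix, build_stc, cumulative_dprime,
    spread_of_excitation, spatial_to_spectral,
)
from ocipipe.synthetic import default_ladder, simulate_optical_trials

model = CochlearModel()                      # 11 mm gerbil scala tympani
probe = RecordingGeometry()                  # 32 electrodes, 50 um pitch
layout = EmitterLayout(pitch_mm=0.25, insertion_depth_mm=3.0)
act = ActivationModel(transduction_profile=1.0)

ladder = default_ladder("block4")            # 0..10 mA split over 4 uLEDs
spikes = simulate_optical_trials(model, layout, act, ladder,
                                 active_set=(4, 5, 6, 7), seed=7, probe=probe)

rm = build_response_matrix(spikes, ladder, ResponseWindow())
stc = build_stc(cumulative_dprime(rm))
print(f"best electrode: {stc.best_electrode} "
      f"(threshold {stc.be_threshold:.2f} mA)")
print(f"max cumulative d': {stc.max_dprime:.2f}, "
      f"active electrodes: {stc.n_active}/32")
for crit in (1.5, 2.0, 2.5, 3.0):
    sp = spread_of_excitation(stc, criterion_dprime=crit, geometry=probe)
    if sp.achieved:
        octs = spatial_to_spectral(sp.span_mm, 4.34)
        print(f"spread @ d'={crit}: {sp.span_mm*1e3:.0f} um in the ICC "
              f"= {octs:.2f} octaves")
```

Output:

```
best electrode: 16 (threshold 2.51 mA)
max cumulative d': 2.07, active electrodes: 9/32
spread @ d'=1.5: 300 um in the ICC = 1.30 octaves
spread @ d'=2.0: 400 um in the ICC = 1.74 octaves
```

Reading it: the block centred 4.1 mm into the cochlea focuses activation on
electrode 16 of the ICC probe, reaches threshold at 2.5 mA total drive, and
at a response strength of d′ = 2 at the best electrode its excitation spans
1.74 octaves of the tonotopic axis — between the acoustic (~1.4 oct) and
monopolar-electrical (~4.9 oct) reference values at the same criterion.
Stronger stimuli spread further: the run never reaches d′ = 2.5 at the BE,
so those criteria are reported as not achieved.

The same analysis is scriptable end to end (simulate → detect → tune → STC
→ spread → report) via the CLI:

```sh
ocipipe run --seed 1 --out runs/demo       # writes CSVs, report.md, manifest.json
ocipipe detect --in trace.csv --fs 32000 --out spikes.csv
ocipipe stc --spikes spikes_optical.csv --condition block4 --out stc/
```

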