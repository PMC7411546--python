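# Methods

`ocipipe` quantifies how focally an optical cochlear implant (oCI) activates
the auditory pathway. The experimental setting it models: spiral ganglion
neurons (SGNs) of adult gerbils are rendered light-sensitive by viral
transfer of a channelrhodopsin; a 16-μLED implant (60 × 60 μm emitters,
pitch 100/150/250 μm) is inserted into the scala tympani; and multi-unit
activity is recorded across the tonotopic axis of the central inferior
colliculus (ICC) with a 32-channel linear probe (50 μm pitch). The analysis
answers two questions: *how strong* is activation for a given optical drive,
and *how spatially (hence spectrally) confined* is it.

## Spike extraction

Extracellular traces (32 kHz) are band-pass filtered at 0.6–6 kHz with a
4th-order Butterworth design applied forward–backward (zero phase, so event
times are not shifted by group delay). Multi-unit time stamps are excursions
of the rectified filtered trace beyond **median + 3 × MAD**, where MAD is
the raw median absolute deviation (no 1.4826 normal-consistency factor).
Each excursion contributes its first suprathreshold sample; a 1 ms
artificial refractory period then suppresses further events, greedily in
time order, to avoid double-counting single multi-unit events. Which
polarity is thresholded is configurable (`absolute` by default; `negative`
or `positive` are available because the underlying convention is ambiguous
in this kind of protocol).

A deliberate property of this threshold: on an unbounded (Gaussian) noise
background it sits near 1.9 in-band SDs, so noise peaks *are* detected at a
substantial stationary rate. That is acceptable — and matches how such
multi-unit analyses behave in practice — because every downstream statistic
is baseline-referenced: the cumulative d′ subtracts the zero-intensity
condition, so a stationary event rate cancels. Consequences worth knowing:
ground-truth F1 is only meaningful against bounded-noise traces (the test
suite scores the detector there, where F1 = 1 at 8× amplitude), and on
Gaussian noise a small fraction of true spikes (~10% at 115 spikes/s) is
lost to refractory collisions with noise events.

## Response quantification

Spikes are counted in a half-open **[3, 20) ms** window after each 1 ms
light pulse (the 3 ms start skips the electrical stimulus artifact). Counts
are sorted into a response matrix over (electrode × intensity), the first
intensity being the zero/no-stimulation baseline, 20 trials per step by
default. The cumulative discrimination index accumulates standardized
increments between adjacent intensity steps,

    Δd′_i = (μ_i − μ_{i−1}) / sqrt((σ_i² + σ_{i−1}²)/2),   d′(0) = 0,

so a response exactly one pooled SD above baseline has d′ = 1. Numerical
safeguards: the pooled SD is floored at 0.5 spikes/window (half a count) so
zero-variance cells cannot produce infinite increments, and each increment
is clipped to |Δd′| ≤ 5. Negative increments (suppression) are kept in the
raw cumulative trace, but thresholds and contours are read from the trace
clipped at 0, because activation thresholds are excitation-defined; both
versions are exported.

Spatial tuning curves (STCs) are iso-contours of cumulative d′ on the
electrode × intensity plane (contour extraction via `contourpy`, the same
marching-squares family as MATLAB's `contour`). Per electrode, the
activation threshold is the linearly interpolated intensity of the first
d′ = 1 crossing, in the ladder's native units (mA for μLED drive, mW for
fiber). The **best electrode (BE)** has the lowest threshold; ties break by
higher maximum d′, then the more dorsal index, so the result is
deterministic.

**Spread of excitation (SoE)** at criterion d′ ∈ {1.5, 2, 2.5, 3}: find the
interpolated intensity at which the BE reaches the criterion, interpolate
every electrode's d′ at that intensity, and span the dorsal-most to
ventral-most electrode with d′ ≥ 1 — sub-threshold gaps inside that range
are bridged (outermost rule) so multi-peaked STCs are not underestimated.
Implants enter the tonotopy analysis only if STCs from ≥ 2 emitters each
reach threshold on ≥ 3 electrodes with maximum d′ ≥ 1.5.

## Tonotopic calibration and place code

Pure tones (100 ms, quarter-octave steps 0.5–32 kHz, levels 20–80 dB SPL by
10 dB, 25 repetitions) yield a frequency response area per electrode. A cell
is *responsive* when its mean rate exceeds the spontaneous rate (estimated
from pre-stimulus spans) by 3 spontaneous SDs; the exact rule used in
comparable published analyses is not standardized, so the factor and SD
source are configuration. The characteristic frequency (CF) is the frequency
responsive at the lowest level, ties broken by higher rate. Per animal,
least squares of log2(CF) on electrode depth gives the tonotopic slope in
octaves/mm; the cohort is summarized by median ± MAD. Deafened animals
cannot be mapped acoustically and are assigned the hearing-cohort median —
also the slope used to convert their spatial spreads to octaves
(`octaves = span_mm × slope`).

For the place code, emitter positions are normalized to the apical-most
responsive emitter of each implant and each STC's BE to that emitter's BE;
regressing relative BE (electrodes) on relative emitter position (mm along
the cochlea) gives the place-code slope, reported with Pearson r and its
two-sided p-value. With 50 μm electrode pitch, 1 electrode = 50 μm of ICC.

## The synthetic cohort

No recordings from this preparation are public, so the package ships a
generator whose defaults define the conditions under which everything is
tested. Per animal (all seeded from one cohort seed via named substreams):

- **Cochlea**: straightened 11 mm place axis with a log-linear
  place–frequency map from 32 kHz (base) to 0.5 kHz (apex), i.e. 0.545
  oct/mm. The log-linear form and endpoints are configurable modelling
  defaults, not measured values.
- **ICC probe**: electrode best frequency = 0.5 kHz × 2^(4.34 × depth), the
  gerbil ICC gradient; per-animal octave jitter (SD 0.25 oct) on the dorsal
  anchor. Electrodes whose best frequency falls outside the tone grid are
  treated as outside the acoustically mapped region and stay at the
  spontaneous rate (20 Hz), mirroring fits restricted to responsive
  electrodes.
- **Acoustic tuning**: V-shaped thresholds (15 dB/octave flanks, tip
  threshold uniform in 25–35 dB SPL), rate growing linearly over 10 dB above
  threshold to 80 Hz; Poisson counts; evoked spikes uniform in the tone
  window at 5 ms latency. Deafened animals produce spontaneous activity
  only.
- **Optics**: per-μLED radiant flux follows a saturating exponential
  F_max(1 − e^(−I/τ)) with F_max = 1.42 mW, τ = 13 mA, calibrated to the
  measured anchors 0.76 mW at 10 mA and ≈0.99 mW for a block of four at
  2.5 mA each (the published single/block/full-array flux figures are not
  mutually consistent; the block anchor was preferred because it is what
  makes block stimulation physically stronger than single-emitter
  stimulation). Flux spreads along the place axis as a 1-D Gaussian
  (σ = 0.3 mm); fiber illumination is flat at 0.1 of the radiant flux per
  mm. 3-D optics are out of scope.
- **Recruitment**: local SGN recruitment is a Hill sigmoid of irradiance ×
  transduction (i50 = 0.2 mW, slope 2) — a calibration placeholder, since no
  measured irradiance–rate relation exists for this opsin/preparation. Each
  animal has a patchy transduction profile (Gaussian-smoothed field,
  correlation length 1 mm, mean 0.5, floor 0.05): patchiness is what makes
  individual μLEDs unreliable activators, reproducing the observed ~⅓
  responsive single emitters and the ordering single < block < all < fiber.
- **ICC pooling**: each recording site pools local recruitment with a
  Gaussian kernel in octave distance (σ = 0.6 oct) around its best
  frequency. Without midbrain-level pooling a 0.3 mm light spread could
  activate only ~2–3 electrodes, contradicting the tens of active sites seen
  in vivo; the kernel width is a modelling default.
- **Timing**: evoked spikes uniform in [latency, latency + duration) —
  3.25/14 ms for transduced animals, 5.0/5.5 ms for the opto-acoustic
  response of non-injected hearing animals, which is additionally weak
  (peak gain 250 Hz, tuned to yield the mild d′ ≈ 2 responses seen without
  opsin) and dorsally biased (0.3 mm space constant). Non-injected deafened
  animals respond to nothing.
- **Rates**: evoked rate = 400 Hz × pooled recruitment on top of 20 Hz
  spontaneous; counts Poisson. Richer peri-stimulus shapes are unnecessary
  for the statistics under test.

What the generator does **not** emulate: real spike waveform diversity and
electrode drift, non-Poisson spike-train statistics (adaptation,
refractoriness of the units themselves), 3-D light propagation, opsin
kinetics, across-trial nonstationarity. Passing tests therefore show the
*analysis* is correct and well-calibrated under these conditions, not that
the biological effect sizes are predicted.

## Problem sizes

The default study conditions are: 11 hearing animals for the acoustic
calibration (25 trials per frequency–level cell, 25 frequencies × 7 levels,
32 electrodes; ≈25 s end to end), 20 trials per intensity step on 8-step
ladders for optical runs, and 4-animal cohorts for the cross-mode
comparisons. Property tests that need replication (place-code recovery,
cohort-bias checks) use reduced protocols (8 emitters / 5 levels / 8–15
trials) chosen so the whole suite stays interactive; the reduced sizes are
stated in each test.

## Known limitations

- CF estimates quantize to the quarter-octave grid; the induced slope error
  (< 1%) is far inside the 5% recovery tolerance but visible at tiny grids.
- The BE of a weak STC (max d′ barely above 1) is noisy across a flat
  recruitment plateau; place-code fits on weak single-μLED data therefore
  show low correlation, as in vivo.
- The flux calibration reconciles inconsistent published anchors; absolute
  thresholds in mW are indicative only.
- `ResponseMatrix` assumes a constant trial count per intensity step.
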