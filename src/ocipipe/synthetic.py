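"""Seeded synthetic stand-ins for every recording the pipeline consumes.

The generator emulates acute multi-channel experiments in which spiral
ganglion neurons (SGNs), rendered light-sensitive by viral opsin transfer,
are stimulated by a 16-μLED optical cochlear implant while multi-unit
activity is recorded on a 32-channel linear probe spanning the tonotopic
axis of the central inferior colliculus (ICC). It produces spike tables for

* acoustic frequency-tuning datasets (V-shaped tuning, Poisson spiking, a
  configurable tonotopic gradient along the probe),
* optical stimulation ladders for single μLEDs, blocks of four, all sixteen,
  and broad fiber illumination, and
* raw extracellular traces with known ground truth for scoring the detector.

The forward model for optical trials is deliberately simple but mechanistic:
radiant flux per emitter follows a saturating-linear current curve; the flux
spreads along the cochlear place axis as a 1-D Gaussian; local SGN
recruitment is a sigmoid of effective irradiance scaled by a patchy
per-animal opsin-transduction profile; and each ICC site pools recruitment
over a Gaussian neighborhood in octave space around its best frequency.
Evoked spikes are Poisson within a fixed latency/duration window on top of
spontaneous activity. Deafened animals lose their acoustic responses but
keep optical ones; non-injected (wild-type) animals have no transduction and
show at most a weak, dorsally biased opto-acoustic response with longer
latency and shorter duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import SPIKE_TABLE_COLUMNS, canonical_sort
from .signal import RawTrace
from .tuning import RecordingGeometry

_GRID_DX_MM = 0.02  # resolution of the internal cochlear place grid

#: quarter-octave pure-tone grid, 0.5–32 kHz
DEFAULT_TONE_FREQS_KHZ = tuple(0.5 * 2 ** (np.arange(25) / 4.0))

LADDER_KINDS = ("single_led", "block4", "all_leds", "fiber", "acoustic")
HEARING_STATUSES = ("hearing", "deaf", "wildtype_hearing", "wildtype_deaf")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CochlearModel:
    """Straightened cochlear place axis with a log-linear place–frequency map.

    Place is measured in mm from the round window (0 = base); frequency
    decreases from ``base_freq_khz`` at the base to ``apex_freq_khz`` at the
    apex. The log-linear form is a modelling default, not a measured gerbil
    map; both endpoints are configurable.
    """

    length_mm: float = 11.0
    base_freq_khz: float = 32.0
    apex_freq_khz: float = 0.5

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ValueError("cochlear length must be positive")
        if self.apex_freq_khz >= self.base_freq_khz:
            raise ValueError("frequency must decrease from base to apex")

    @property
    def octaves_per_mm(self) -> float:
        return np.log2(self.base_freq_khz / self.apex_freq_khz) / self.length_mm

    def freq_at(self, place_mm):
        """Frequency (kHz) at a place (mm from the round window)."""
        return self.base_freq_khz * 2.0 ** (-self.octaves_per_mm * np.asarray(place_mm, dtype=float))

    def place_at(self, freq_khz):
        """Inverse map: place (mm) of a frequency (kHz)."""
        return np.log2(self.base_freq_khz / np.asarray(freq_khz, dtype=float)) / self.octaves_per_mm


@dataclass(frozen=True)
class EmitterLayout:
    """μLED positions on the implant, most basal emitter first.

    ``insertion_depth_mm`` is the cochlear place of the most basal emitter;
    emitters advance apically in steps of ``pitch_mm``.
    """

    n_emitters: int = 16
    pitch_mm: float = 0.100
    insertion_depth_mm: float = 3.0
    emitter_size_um: float = 60.0
    functional_mask: tuple[bool, ...] | None = None

    def __post_init__(self):
        if self.n_emitters < 1 or self.pitch_mm <= 0:
            raise ValueError("invalid emitter layout")
        if self.functional_mask is not None and len(self.functional_mask) != self.n_emitters:
            raise ValueError("functional_mask length must equal n_emitters")

    @property
    def span_mm(self) -> float:
        return (self.n_emitters - 1) * self.pitch_mm

    def positions_mm(self) -> np.ndarray:
        return self.insertion_depth_mm + np.arange(self.n_emitters) * self.pitch_mm

    def functional_emitters(self) -> list[int]:
        if self.functional_mask is None:
            return list(range(self.n_emitters))
        return [i for i, ok in enumerate(self.functional_mask) if ok]


@dataclass(frozen=True)
class StimulusLadder:
    """Ordered intensity ladder for one stimulation mode.

    Intensities are total driving current (mA) for μLED modes — split equally
    across active emitters for ``block4``/``all_leds`` — radiant flux (mW)
    for ``fiber``, and dB SPL for ``acoustic``. The first step is always the
    zero-intensity (no stimulation) baseline condition.
    """

    kind: str
    intensities: tuple[float, ...]
    pulse_ms: float = 1.0
    n_trials_per_step: int = 20
    flux_max_mw: float = 1.42
    flux_tau_ma: float = 13.0

    def __post_init__(self):
        if self.kind not in LADDER_KINDS:
            raise ValueError(f"unknown ladder kind {self.kind!r}")
        ints = np.asarray(self.intensities, dtype=float)
        if ints.size < 2 or np.any(np.diff(ints) <= 0):
            raise ValueError("intensities must be strictly increasing with >= 2 steps")
        if ints[0] != 0:
            raise ValueError("first intensity must be exactly 0 (baseline condition)")
        if self.pulse_ms <= 0 or self.n_trials_per_step < 1:
            raise ValueError("invalid pulse duration or trial count")

    def flux_per_current(self, current_ma):
        """Radiant flux (mW) of one μLED at a driving current (mA).

        Saturating exponential ``F_max (1 − exp(−I/τ))`` calibrated to the
        measured anchors 0.76 mW at 10 mA and ≈0.99 mW for a block of four
        at 2.5 mA each; sixteen emitters at 2.5 mA then give ≈3.96 mW total.
        """
        i = np.asarray(current_ma, dtype=float)
        return self.flux_max_mw * (1.0 - np.exp(-i / self.flux_tau_ma))


def default_ladder(kind: str, n_trials: int = 20) -> StimulusLadder:
    """Default intensity ladders per stimulation mode (see class docs for units)."""
    ladders = {
        "single_led": (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0),
        "block4": (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0),
        "all_leds": (0.0, 2.0, 4.0, 8.0, 12.0, 20.0, 30.0, 40.0),
        "fiber": (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 35.0),
    }
    if kind not in ladders:
        raise ValueError(f"no default ladder for kind {kind!r}")
    return StimulusLadder(kind=kind, intensities=ladders[kind],
                          n_trials_per_step=n_trials)


def default_acoustic_ladder(n_trials: int = 25) -> StimulusLadder:
    """Sound-level ladder for frequency tuning: baseline + 20–80 dB SPL."""
    return StimulusLadder(
        kind="acoustic",
        intensities=(0.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0),
        pulse_ms=100.0,
        n_trials_per_step=n_trials,
    )


@dataclass(frozen=True)
class ActivationModel:
    """Parameters of the irradiance → firing forward model for one animal.

    The sigmoid recruitment curve is a calibration placeholder (no measured
    irradiance–rate relation exists for CatCh-expressing SGNs); its defaults
    were chosen once so that the four stimulation modes reproduce the ordinal
    response structure single < block-of-4 < all-16 < fiber.
    """

    light_sigma_mm: float = 0.3
    rate_max_hz: float = 400.0
    i50_mw: float = 0.2
    hill_slope: float = 2.0
    baseline_rate_hz: float = 20.0
    latency_ms: float = 3.25
    duration_ms: float = 14.0
    tonotopic_slope_oct_per_mm: float = 4.34
    bf_dorsal_khz: float = 0.5
    icc_sigma_oct: float = 0.6
    #: per-place opsin expression in [0, 1]: scalar, or an array sampled on
    #: ``place_grid(model)``; 0 models a non-injected (wild-type) animal
    transduction_profile: object = 1.0
    #: peak added rate of the opto-acoustic response (wild-type hearing only)
    optoacoustic_gain_hz: float = 0.0

    def __post_init__(self):
        if min(self.rate_max_hz, self.baseline_rate_hz, self.latency_ms) < 0:
            raise ValueError("rates and latency must be non-negative")
        if self.light_sigma_mm <= 0 or self.i50_mw <= 0 or self.hill_slope <= 0:
            raise ValueError("light spread and sigmoid parameters must be positive")

    def best_frequency(self, depth_mm):
        """Generative best frequency (kHz) of an ICC site at a probe depth."""
        return self.bf_dorsal_khz * 2.0 ** (
            self.tonotopic_slope_oct_per_mm * np.asarray(depth_mm, dtype=float)
        )

    def recruitment(self, irradiance_mw):
        """Sigmoidal fraction of local SGNs recruited by an effective irradiance."""
        i = np.asarray(irradiance_mw, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = i ** self.hill_slope
            out = np.where(i > 0, h / (h + self.i50_mw ** self.hill_slope), 0.0)
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and the master seed for all per-animal substreams."""

    n_animals: int
    hearing_status: tuple[str, ...]
    seed: int
    rate_jitter_sigma: float = 0.2
    i50_jitter_sigma: float = 0.2
    bf_jitter_oct: float = 0.25

    def __post_init__(self):
        if len(self.hearing_status) != self.n_animals:
            raise ValueError("hearing_status must list one status per animal")
        for s in self.hearing_status:
            if s not in HEARING_STATUSES:
                raise ValueError(f"unknown hearing status {s!r}")
        if self.seed is None:
            raise ValueError("a cohort seed is mandatory")


@dataclass
class AnimalInstance:
    """One simulated animal: id, status and its jittered activation model."""

    animal_id: str
    status: str
    act: ActivationModel
    seed_seq: np.random.SeedSequence

    @property
    def hears(self) -> bool:
        return self.status in ("hearing", "wildtype_hearing")

    @property
    def transduced(self) -> bool:
        return self.status in ("hearing", "deaf")

    def spawn_seed(self, label: str) -> np.random.SeedSequence:
        """Deterministic named substream for one simulation step."""
        digest = np.frombuffer(
            label.encode().ljust(8, b"\0")[:8], dtype=np.uint32
        )
        return np.random.SeedSequence(
            entropy=self.seed_seq.entropy,
            spawn_key=tuple(self.seed_seq.spawn_key) + tuple(int(d) for d in digest),
        )


# ---------------------------------------------------------------------------
# cohort construction


def place_grid(model: CochlearModel) -> np.ndarray:
    return np.arange(0.0, model.length_mm + _GRID_DX_MM / 2, _GRID_DX_MM)


def make_transduction_profile(
    model: CochlearModel,
    rng: np.random.Generator,
    *,
    mean: float = 0.5,
    sd: float = 0.35,
    corr_mm: float = 1.0,
    floor: float = 0.05,
) -> np.ndarray:
    """Patchy opsin-expression profile along the place axis.

    A Gaussian-smoothed noise field (correlation length ``corr_mm``) shifted
    to ``mean`` and clipped to [floor, 1]. Patchiness is what makes single
    μLEDs unreliable activators while blocks and full-array stimulation,
    which integrate over more of the spiral ganglion, respond robustly.
    """
    x = place_grid(model)
    z = gaussian_filter1d(rng.standard_normal(x.size), corr_mm / _GRID_DX_MM,
                          mode="reflect")
    z = (z - z.mean()) / (z.std() + 1e-12)
    return np.clip(mean + sd * z, floor, 1.0)


def draw_cohort(spec: CohortSpec, model: CochlearModel = CochlearModel()) -> list[AnimalInstance]:
    """Instantiate per-animal activation models with multiplicative jitter.

    A single cohort seed deterministically derives one substream per animal;
    log-normal jitter on ``rate_max_hz`` and ``i50_mw`` and an octave offset
    on the probe's dorsal best frequency reproduce across-animal variability.
    Wild-type animals get a zero transduction profile, the opto-acoustic
    latency/duration (5.0 / 5.5 ms), and — if hearing — a weak opto-acoustic
    response; deafened wild-types respond to nothing.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_animals)
    animals = []
    for i, (status, ss) in enumerate(zip(spec.hearing_status, streams)):
        rng = np.random.default_rng(ss.spawn(1)[0])
        base = ActivationModel()
        kw = dict(
            rate_max_hz=base.rate_max_hz * rng.lognormal(0.0, spec.rate_jitter_sigma),
            i50_mw=base.i50_mw * rng.lognormal(0.0, spec.i50_jitter_sigma),
            bf_dorsal_khz=base.bf_dorsal_khz
            * 2.0 ** rng.normal(0.0, spec.bf_jitter_oct),
        )
        if status.startswith("wildtype"):
            kw.update(
                transduction_profile=0.0,
                latency_ms=5.0,
                duration_ms=5.5,
                # calibrated so maximal full-array drive yields the mild
                # (d' ~ 2) responses seen in non-injected hearing ears
                optoacoustic_gain_hz=250.0 if status == "wildtype_hearing" else 0.0,
            )
        else:
            kw.update(transduction_profile=make_transduction_profile(model, rng))
        animals.append(
            AnimalInstance(
                animal_id=f"a{i + 1:02d}",
                status=status,
                act=replace(base, **kw),
                seed_seq=ss,
            )
        )
    return animals


def emitter_sets(layout: EmitterLayout, mode: str) -> list[tuple[int, ...]]:
    """Active-emitter combinations driven in one mode.

    ``single_led`` drives each functional emitter in turn, ``block4`` each
    contiguous block of four, ``all_leds`` every functional emitter at once,
    ``fiber`` none (broad illumination).
    """
    functional = layout.functional_emitters()
    if mode == "single_led":
        return [(e,) for e in functional]
    if mode == "block4":
        blocks = []
        for start in range(0, layout.n_emitters - 3, 4):
            block = tuple(e for e in range(start, start + 4) if e in functional)
            if block:
                blocks.append(block)
        return blocks
    if mode == "all_leds":
        return [tuple(functional)]
    if mode == "fiber":
        return [()]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# helpers


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _expand_counts(counts: np.ndarray, lo, hi, rng) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a count array into (flat_cell_index, uniform spike times)."""
    flat = counts.ravel()
    idx = np.repeat(np.arange(flat.size), flat)
    t = rng.uniform(lo, hi, idx.size)
    return idx, t


def _table_from_counts(
    counts_list,
    axes_shape,
    idx_to_columns,
    animal_id: str,
    condition: str,
) -> pd.DataFrame:
    """Assemble spike-table rows from (counts, lo, hi, rng) specs."""
    frames = []
    for counts, lo, hi, rng in counts_list:
        idx, t = _expand_counts(counts, lo, hi, rng)
        cols = idx_to_columns(np.unravel_index(idx, axes_shape))
        cols["t_ms"] = t
        cols["animal_id"] = animal_id
        cols["condition"] = condition
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SPIKE_TABLE_COLUMNS
    )
    return canonical_sort(table[SPIKE_TABLE_COLUMNS])


def _transduction_on_grid(act: ActivationModel, x: np.ndarray) -> np.ndarray:
    prof = act.transduction_profile
    if np.isscalar(prof):
        return np.full(x.size, float(prof))
    prof = np.asarray(prof, dtype=float)
    if prof.size != x.size:
        raise ValueError(
            "transduction_profile array must be sampled on place_grid(model)"
        )
    return prof


# ---------------------------------------------------------------------------
# generators


def simulate_fra_dataset(
    model: CochlearModel,
    probe: RecordingGeometry,
    act: ActivationModel,
    acoustic: StimulusLadder,
    seed,
    *,
    animal_id: str = "a01",
    hearing: bool = True,
    freqs_khz: Sequence[float] = DEFAULT_TONE_FREQS_KHZ,
    rate_max_acoustic_hz: float = 80.0,
    v_slope_db_per_oct: float = 15.0,
    growth_db: float = 10.0,
    threshold_range_db: tuple[float, float] = (25.0, 35.0),
    tone_ms: float = 100.0,
    acoustic_latency_ms: float = 5.0,
    pre_ms: float = 50.0,
    post_ms: float = 150.0,
) -> pd.DataFrame:
    """Simulate an acoustic frequency-tuning dataset for one animal.

    Each electrode has a best frequency set by its depth through the
    configured tonotopic gradient and V-shaped thresholds rising by
    ``v_slope_db_per_oct`` away from it; evoked rates grow linearly over
    ``growth_db`` above threshold up to ``rate_max_acoustic_hz``. Counts are
    Poisson; evoked spikes fall in the tone window, spontaneous spikes cover
    the whole trial span ``[-pre_ms, post_ms)``. Electrodes whose best
    frequency lies outside the tone grid are treated as outside the
    acoustically mapped ICC region (spontaneous activity only), as are all
    electrodes of deafened animals.
    """
    if acoustic.kind != "acoustic":
        raise ValueError("simulate_fra_dataset needs an acoustic ladder")
    freqs = np.sort(np.asarray(freqs_khz, dtype=float))
    if np.log2(freqs[-1] / freqs[0]) < 2:
        raise ValueError("tone grid must span at least 2 octaves")
    levels = np.asarray(acoustic.intensities, dtype=float)
    n_trials = acoustic.n_trials_per_step
    rng = _rng(seed)

    depths = probe.depths_mm()
    bf = act.best_frequency(depths)  # (E,)
    thr_cf = rng.uniform(*threshold_range_db, size=probe.n_electrodes)
    mapped = (bf >= freqs[0]) & (bf <= freqs[-1])
    responsive = mapped if hearing else np.zeros_like(mapped)

    doct = np.abs(np.log2(freqs[None, :] / bf[:, None]))  # (E, F)
    thr = thr_cf[:, None] + v_slope_db_per_oct * doct
    drive = np.clip((levels[None, None, :] - thr[:, :, None]) / growth_db, 0.0, 1.0)
    evoked_rate = rate_max_acoustic_hz * drive * responsive[:, None, None]

    shape = (probe.n_electrodes, freqs.size, levels.size, n_trials)
    lam_ev = np.broadcast_to(evoked_rate[..., None] * tone_ms * 1e-3, shape)
    n_ev = rng.poisson(lam_ev)
    span_s = (pre_ms + post_ms) * 1e-3
    n_sp = rng.poisson(act.baseline_rate_hz * span_s, size=shape)

    def cols(ix):
        e, f, l, tr = ix
        return {
            "emitter_set": np.char.mod("%.6g", freqs[f]),
            "intensity": levels[l],
            "trial": tr,
            "electrode": e + 1,
        }

    return _table_from_counts(
        [
            (n_ev, acoustic_latency_ms, acoustic_latency_ms + tone_ms, rng),
            (n_sp, -pre_ms, post_ms, rng),
        ],
        shape,
        cols,
        animal_id,
        "acoustic",
    )


def effective_irradiance(
    model: CochlearModel,
    layout: EmitterLayout,
    ladder: StimulusLadder,
    active_set: Sequence[int],
    intensity: float,
    *,
    light_sigma_mm: float = 0.3,
    fiber_coupling_per_mm: float = 0.1,
) -> np.ndarray:
    """Irradiance profile (mW) along ``place_grid(model)`` for one step.

    μLED modes: per-emitter flux (total current split equally across the
    active set for block/all-array drive) spread as a 1-D Gaussian of width
    ``light_sigma_mm`` along the place axis. Fiber: flat broad illumination
    at ``fiber_coupling_per_mm`` of the radiant flux per mm of cochlea.
    """
    x = place_grid(model)
    if ladder.kind == "fiber":
        return np.full(x.size, intensity * fiber_coupling_per_mm)
    if not active_set:
        raise ValueError("active_set must be non-empty for μLED stimulation")
    positions = layout.positions_mm()
    per_emitter_ma = intensity if ladder.kind == "single_led" else intensity / len(active_set)
    flux = ladder.flux_per_current(per_emitter_ma)
    out = np.zeros(x.size)
    for e in active_set:
        out += flux * np.exp(-((x - positions[e]) ** 2) / (2 * light_sigma_mm**2))
    return out


def electrode_recruitment(
    model: CochlearModel,
    probe: RecordingGeometry,
    act: ActivationModel,
    irradiance: np.ndarray,
) -> np.ndarray:
    """Fraction of drive pooled by each ICC site for one irradiance profile.

    Local SGN recruitment (sigmoid of irradiance × transduction) is pooled
    with a Gaussian kernel in octave distance between the cochlear place
    frequency and the site's best frequency, normalized so that full
    recruitment everywhere gives 1.
    """
    x = place_grid(model)
    t_prof = _transduction_on_grid(act, x)
    local = act.recruitment(irradiance * t_prof)  # (X,)
    f_place_oct = np.log2(model.freq_at(x))  # (X,)
    bf_oct = np.log2(act.best_frequency(probe.depths_mm()))  # (E,)
    w = np.exp(
        -((bf_oct[:, None] - f_place_oct[None, :]) ** 2) / (2 * act.icc_sigma_oct**2)
    )
    sigma_place_mm = act.icc_sigma_oct / model.octaves_per_mm
    norm = sigma_place_mm * np.sqrt(2 * np.pi)
    rho = (w @ local) * _GRID_DX_MM / norm
    return np.clip(rho, 0.0, 1.0)


def simulate_optical_trials(
    model: CochlearModel,
    layout: EmitterLayout,
    act: ActivationModel,
    ladder: StimulusLadder,
    active_set: Sequence[int],
    seed,
    *,
    probe: RecordingGeometry = RecordingGeometry(),
    animal_id: str = "a01",
    hearing_hair_cells: bool = False,
    trial_start_ms: float = 0.0,
    trial_span_ms: float = 50.0,
) -> pd.DataFrame:
    """Simulate one optical stimulation run (all ladder steps, all trials).

    Evoked counts on each of the 32 electrodes are Poisson with rate
    ``rate_max_hz`` × pooled recruitment, with spikes drawn uniformly within
    ``[latency, latency + duration)``; spontaneous activity at
    ``baseline_rate_hz`` covers the whole trial span
    ``[trial_start_ms, trial_start_ms + trial_span_ms)``, so the
    zero-intensity step still emits baseline spikes. ``hearing_hair_cells``
    enables the opto-acoustic pathway (used for non-injected hearing animals).
    """
    rng = _rng(seed)
    if ladder.kind == "acoustic":
        raise ValueError("use simulate_fra_dataset for acoustic stimulation")
    active_set = tuple(sorted(active_set))
    if ladder.kind != "fiber":
        functional = set(layout.functional_emitters())
        if not active_set:
            raise ValueError("active_set must be non-empty")
        if not set(active_set) <= functional:
            raise ValueError("active_set includes non-functional emitters")
        positions = layout.positions_mm()
        if np.any(positions[list(active_set)] < 0) or np.any(
            positions[list(active_set)] > model.length_mm
        ):
            raise ValueError("active emitter lies outside the cochlea")

    intensities = np.asarray(ladder.intensities, dtype=float)
    n_trials = ladder.n_trials_per_step
    n_el = probe.n_electrodes

    rate = np.zeros((intensities.size, n_el))
    for k, inten in enumerate(intensities):
        if inten == 0:
            continue
        irr = effective_irradiance(
            model, layout, ladder, active_set, inten,
            light_sigma_mm=act.light_sigma_mm,
        )
        rho = electrode_recruitment(model, probe, act, irr)
        rate[k] = act.rate_max_hz * rho
        if act.optoacoustic_gain_hz > 0 and hearing_hair_cells:
            rate[k] += _optoacoustic_rate(model, probe, act, irr)

    shape = (intensities.size, n_el, n_trials)
    dur_s = act.duration_ms * 1e-3
    n_ev = rng.poisson(np.broadcast_to(rate[:, :, None] * dur_s, shape))
    n_sp = rng.poisson(act.baseline_rate_hz * trial_span_ms * 1e-3, size=shape)

    label = "+".join(map(str, active_set)) if active_set else "fiber"

    def cols(ix):
        k, e, tr = ix
        return {
            "emitter_set": np.full(k.size, label),
            "intensity": intensities[k],
            "trial": tr,
            "electrode": e + 1,
        }

    return _table_from_counts(
        [
            (n_ev, act.latency_ms, act.latency_ms + act.duration_ms, rng),
            (n_sp, trial_start_ms, trial_start_ms + trial_span_ms, rng),
        ],
        shape,
        cols,
        animal_id,
        ladder.kind,
    )


def _optoacoustic_rate(model, probe, act, irradiance) -> np.ndarray:
    """Weak, dorsally biased response of hair-cell origin in non-injected ears.

    Scales with total radiant flux (half-max ~1.5 mW), decays ventrally with
    0.3 mm space constant — the responses sit in low-frequency, dorsal ICC
    regions that do not tonotopically match the illuminated basal cochlea.
    """
    total_flux = float(np.trapezoid(irradiance, dx=_GRID_DX_MM) / 0.752)
    drive = total_flux**2 / (total_flux**2 + 1.5**2)
    depths = probe.depths_mm()
    return act.optoacoustic_gain_hz * drive * np.exp(
        -(depths - depths[0]) / 0.3
    )


def implied_place_code_slope(
    model: CochlearModel,
    act: ActivationModel,
    probe: RecordingGeometry = RecordingGeometry(),
) -> float:
    """BE shift (electrodes) per mm of emitter place implied by the mappings.

    One mm along the cochlea spans ``model.octaves_per_mm`` octaves, which
    the ICC map covers in ``octaves / tonotopic_slope`` mm of probe depth.
    """
    return model.octaves_per_mm / act.tonotopic_slope_oct_per_mm / probe.pitch_mm


def default_spike_kernel(fs_hz: float, width_ms: float = 0.6) -> np.ndarray:
    """Biphasic (negative-leading) extracellular waveform, unit peak amplitude."""
    n = max(int(round(width_ms * 1e-3 * fs_hz)), 5)
    t = np.linspace(0, 1, n)
    w = -np.sin(2 * np.pi * t) * np.hanning(n)
    return w / np.max(np.abs(w))


def simulate_raw_trace(
    spikes,
    waveform_kernel: np.ndarray | None = None,
    noise_sd: float = 1.0,
    fs: float = 32000.0,
    seed=None,
    *,
    amplitude: float = 8.0,
    duration_ms: float | None = None,
    t0_ms: float = 0.0,
    noise: str = "gaussian",
) -> RawTrace:
    """Render ground-truth spike times into a noisy extracellular trace.

    ``spikes`` is an array of times (ms, relative to onset) or a spike-table
    slice with a ``t_ms`` column. The trace is noise of SD ``noise_sd`` plus
    the kernel scaled by ``amplitude`` at each spike time; spikes closer
    together than the kernel support trigger an overlap warning (they would
    merge in the trace). ``noise`` selects Gaussian (unbounded, so a robust
    median + MAD threshold will also pick up noise peaks, as on real
    recordings) or uniform (bounded; no detectable noise peaks, useful for
    exact ground-truth scoring of the detector).
    """
    if fs < 20000:
        raise ValueError("sampling rate must be at least 20 kHz")
    if isinstance(spikes, pd.DataFrame):
        times = spikes["t_ms"].to_numpy(dtype=float)
    else:
        times = np.asarray(spikes, dtype=float)
    kernel = default_spike_kernel(fs) if waveform_kernel is None else np.asarray(
        waveform_kernel, dtype=float
    )
    support_ms = kernel.size / fs * 1e3
    if times.size > 1:
        if np.min(np.diff(np.sort(times))) < support_ms:
            warnings.warn("spikes closer than the kernel support overlap in the trace")
    if duration_ms is None:
        duration_ms = (np.max(times) if times.size else 0.0) + t0_ms + 5 * support_ms
    n = int(round(duration_ms * 1e-3 * fs))
    rng = _rng(seed)
    if noise_sd <= 0:
        trace = np.zeros(n)
    elif noise == "gaussian":
        trace = rng.standard_normal(n) * noise_sd
    elif noise == "uniform":
        a = noise_sd * np.sqrt(3.0)  # matches the requested SD
        trace = rng.uniform(-a, a, n)
    else:
        raise ValueError(f"unknown noise kind {noise!r}")
    for t in times:
        i0 = int(round((t + t0_ms) * 1e-3 * fs))
        i1 = min(i0 + kernel.size, n)
        if i0 < 0 or i0 >= n:
            raise ValueError(f"spike at {t} ms falls outside the trace")
        trace[i0:i1] += amplitude * kernel[: i1 - i0]
    return RawTrace(trace, fs, t0_ms)
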