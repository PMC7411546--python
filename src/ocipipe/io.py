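"""Spike-table I/O, run configuration, and the end-to-end pipeline driver.

The pipeline's interchange currency is the *spike table*: a long-format
:class:`pandas.DataFrame` with one row per detected spike and columns

``animal_id, condition, emitter_set, intensity, trial, electrode, t_ms``

* ``condition`` — stimulus family: ``acoustic``, ``single_led``, ``block4``,
  ``all_leds`` or ``fiber``.
* ``emitter_set`` — stimulus identity within the family: ``+``-joined emitter
  indices for optical runs (``"3"``, ``"0+1+2+3"``), the tone frequency in kHz
  for acoustic runs, ``"fiber"`` for fiber runs.
* ``intensity`` — driving current (mA), radiant flux (mW) or sound level
  (dB SPL); the zero entry is the no-stimulation baseline.
* ``electrode`` — 1-based recording-site index, 1 = most dorsal.
* ``t_ms`` — spike time in ms relative to stimulus onset.

Tables are stored as plain CSV so that every intermediate of a run stays
inspectable with standard tools.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SPIKE_TABLE_COLUMNS = [
    "animal_id",
    "condition",
    "emitter_set",
    "intensity",
    "trial",
    "electrode",
    "t_ms",
]

_DTYPES = {
    "animal_id": str,
    "condition": str,
    "emitter_set": str,
    "intensity": float,
    "trial": int,
    "electrode": int,
    "t_ms": float,
}


def empty_spike_table() -> pd.DataFrame:
    """Return an empty spike table with the canonical schema."""
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})


def canonical_sort(table: pd.DataFrame) -> pd.DataFrame:
    """Sort a spike table into its canonical row order (stable, reproducible)."""
    return table.sort_values(
        SPIKE_TABLE_COLUMNS[:-1] + ["t_ms"], kind="mergesort"
    ).reset_index(drop=True)


def validate_spike_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and coerce dtypes; raise ``ValueError`` naming any problem."""
    missing = [c for c in SPIKE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike table is missing column(s): {', '.join(missing)}")
    out = table[SPIKE_TABLE_COLUMNS].copy()
    for col, dtype in _DTYPES.items():
        try:
            out[col] = out[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            bad = out[col].iloc[:1].tolist()
            raise ValueError(
                f"column {col!r} cannot be read as {dtype.__name__} "
                f"(first value: {bad})"
            ) from exc
    if (out["electrode"] < 1).any():
        row = int(np.argmax(out["electrode"].to_numpy() < 1))
        raise ValueError(f"electrode indices are 1-based; row {row} violates this")
    return out


def write_spike_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_spike_table(table).pipe(canonical_sort).to_csv(path, index=False)


def read_spike_table(path: str | Path) -> pd.DataFrame:
    """Read a spike-table CSV, validating the schema.

    Rows may be in any order on disk; the returned frame is canonically
    sorted so that downstream results do not depend on storage order.
    """
    try:
        raw = pd.read_csv(path, dtype={"emitter_set": str, "animal_id": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: not a parseable CSV spike table: {exc}") from exc
    return canonical_sort(validate_spike_table(raw))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of a full simulate → analyse run.

    Analysis parameters default to the values used throughout the package:
    3–20 ms response window, spread criteria d' = 1.5/2/2.5/3, spike
    detection at median + 3 MAD in the 0.6–6 kHz band.
    """

    seed: int = 0
    outdir: str = "ocipipe_run"
    n_hearing: int = 2
    n_deaf: int = 1
    emitter_pitch_mm: float = 0.25
    insertion_depth_mm: float = 3.0
    modes: tuple[str, ...] = ("single_led", "block4", "all_leds", "fiber")
    fra_trials: int = 25
    optical_trials: int = 20
    window_ms: tuple[float, float] = (3.0, 20.0)
    criteria: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0)
    mad_k: float = 3.0
    band_hz: tuple[float, float] = (600.0, 6000.0)
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("modes", "criteria", "window_ms", "band_hz"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Fingerprint of the analysis-relevant configuration.

        Excludes ``outdir`` and ``verbosity`` so the same scientific run
        hashes identically wherever it is written.
        """
        skip = {"outdir", "verbosity"}
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)
             if k not in skip},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, extra: dict | None = None) -> dict:
    """Hash every file in ``outdir`` into ``manifest.json`` (written last).

    The manifest contains only file names, sizes and SHA-256 digests plus the
    run's seed/config hash, so identical (config, seed) runs are byte-identical.
    """
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {
            str(p.relative_to(outdir)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in files
        }
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → response matrices → d' → STC → spread → report.

    Returns the output manifest. Every stochastic step derives from
    ``config.seed``, so re-running with the same config yields byte-identical
    outputs. Deaf animals contribute no acoustic data; their spatial spreads
    are converted to octaves with the hearing-cohort median tonotopic slope,
    as in the underlying experimental protocol.
    """
    # local imports keep module import cheap and avoid cycles
    from . import placecode, stc as stc_mod, synthetic, tuning

    if config.n_hearing + config.n_deaf == 0:
        raise ValueError("empty cohort: need at least one animal")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = synthetic.CochlearModel()
    probe = tuning.RecordingGeometry()
    layout = synthetic.EmitterLayout(
        pitch_mm=config.emitter_pitch_mm,
        insertion_depth_mm=config.insertion_depth_mm,
    )
    status = ("hearing",) * config.n_hearing + ("deaf",) * config.n_deaf
    spec = synthetic.CohortSpec(
        n_animals=len(status), hearing_status=status, seed=config.seed
    )
    animals = synthetic.draw_cohort(spec, model)

    from .signal import ResponseWindow

    win = ResponseWindow(*config.window_ms)

    # --- acoustic calibration (hearing animals only) -----------------------
    acoustic_ladder = synthetic.default_acoustic_ladder(config.fra_trials)
    fra_tables, fits, cf_rows = [], [], []
    for animal in animals:
        if not animal.hears:
            continue
        table = synthetic.simulate_fra_dataset(
            model, probe, animal.act, acoustic_ladder, animal.spawn_seed("fra"),
            animal_id=animal.animal_id, hearing=True,
        )
        fra_tables.append(table)
        results = tuning.tune_all_electrodes(
            table, probe, freqs_khz=synthetic.DEFAULT_TONE_FREQS_KHZ,
            levels_db=np.asarray(acoustic_ladder.intensities[1:], dtype=float),
            n_trials=acoustic_ladder.n_trials_per_step,
        )
        fits.append(
            tuning.fit_tonotopic_slope(results, probe, animal_id=animal.animal_id)
        )
        for res in results:
            cf_rows.append(
                {
                    "animal_id": animal.animal_id,
                    "electrode": res.electrode,
                    "depth_mm": probe.depths_mm()[res.electrode - 1],
                    "cf_khz": res.cf_khz,
                    "threshold_db": res.threshold_db,
                    "responsive": res.responsive,
                }
            )
    if fra_tables:
        write_spike_table(pd.concat(fra_tables, ignore_index=True),
                          outdir / "spikes_acoustic.csv")
    pd.DataFrame(cf_rows).to_csv(outdir / "cf_table.csv", index=False)
    valid_fits = [f for f in fits if f.valid]
    if valid_fits:
        median_slope, slope_mad = tuning.cohort_slope_summary(valid_fits)
    else:
        # all-deaf cohort: fall back to the reference gerbil gradient
        median_slope, slope_mad = animals[0].act.tonotopic_slope_oct_per_mm, float("nan")
    pd.DataFrame(
        [
            {
                "animal_id": f.animal_id,
                "slope_oct_per_mm": f.slope_oct_per_mm,
                "intercept_oct": f.intercept_oct,
                "pearson_r": f.pearson_r,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    ).to_csv(outdir / "tonotopy_fits.csv", index=False)

    # --- optical stimulation ----------------------------------------------
    optical_tables, stc_rows, spread_rows, place_rows = [], [], [], []
    for animal in animals:
        slope = median_slope
        for fit in fits:
            if fit.animal_id == animal.animal_id and fit.valid:
                slope = fit.slope_oct_per_mm
        stcs_single: dict[int, "stc_mod.SpatialTuningCurve"] = {}
        stcs_block: dict[int, "stc_mod.SpatialTuningCurve"] = {}
        for mode in config.modes:
            ladder = synthetic.default_ladder(mode, n_trials=config.optical_trials)
            for active in synthetic.emitter_sets(layout, mode):
                table = synthetic.simulate_optical_trials(
                    model, layout, animal.act, ladder, active,
                    animal.spawn_seed(f"{mode}:{active}"),
                    probe=probe, animal_id=animal.animal_id,
                )
                optical_tables.append(table)
                rm = stc_mod.build_response_matrix(
                    table, ladder, win, n_electrodes=probe.n_electrodes
                )
                dp = stc_mod.cumulative_dprime(rm)
                curve = stc_mod.build_stc(dp)
                stc_rows.append(
                    {
                        "animal_id": animal.animal_id,
                        "condition": mode,
                        "emitter_set": "+".join(map(str, active)) if active else "fiber",
                        "max_dprime": curve.max_dprime,
                        "n_active": curve.n_active,
                        "best_electrode": curve.best_electrode,
                        "be_threshold": curve.thresholds[curve.best_electrode - 1]
                        if curve.best_electrode
                        else np.nan,
                    }
                )
                if mode == "single_led" and active:
                    stcs_single[active[0]] = curve
                if mode == "block4" and active:
                    stcs_block[active[0]] = curve
                for crit in config.criteria:
                    sp = stc_mod.spread_of_excitation(
                        curve, criterion_dprime=crit, geometry=probe
                    )
                    spread_rows.append(
                        {
                            "animal_id": animal.animal_id,
                            "condition": mode,
                            "emitter_set": "+".join(map(str, active)) if active else "fiber",
                            "criterion_dprime": crit,
                            "achieved": sp.achieved,
                            "span_mm": sp.span_mm,
                            "span_octaves": placecode.spatial_to_spectral(sp.span_mm, slope)
                            if sp.achieved
                            else np.nan,
                        }
                    )
        for mode, stcs in (("single", stcs_single), ("block4", stcs_block)):
            if stcs and stc_mod.qualify_stc(stcs.values()):
                for pt in placecode.normalize_be_positions(
                    stcs, layout, animal_id=animal.animal_id, mode=mode
                ):
                    place_rows.append(
                        {
                            "animal_id": pt.animal_id,
                            "emitter_mode": pt.emitter_mode,
                            "emitter_position_mm": pt.emitter_position_mm,
                            "relative_be_electrodes": pt.relative_be_electrodes,
                        }
                    )

    if optical_tables:
        write_spike_table(pd.concat(optical_tables, ignore_index=True),
                          outdir / "spikes_optical.csv")
    stc_df = pd.DataFrame(stc_rows)
    stc_df.to_csv(outdir / "stc_summary.csv", index=False)
    spread_df = pd.DataFrame(spread_rows)
    spread_df.to_csv(outdir / "spreads.csv", index=False)
    place_df = pd.DataFrame(place_rows)
    place_df.to_csv(outdir / "placecode_points.csv", index=False)

    place_fit = None
    if len(place_df) >= 3 and place_df["emitter_position_mm"].nunique() > 1:
        place_fit = placecode.fit_place_code(
            [
                placecode.PlaceCodePoint(r.emitter_position_mm,
                                         r.relative_be_electrodes,
                                         r.animal_id, r.emitter_mode)
                for r in place_df.itertuples()
            ]
        )

    _write_report(outdir, config, median_slope, slope_mad, len(valid_fits),
                  stc_df, spread_df, place_fit, probe)
    return write_manifest(
        outdir, extra={"seed": config.seed, "config_hash": config.config_hash()}
    )


def _write_report(outdir, config, median_slope, slope_mad, n_fits,
                  stc_df, spread_df, place_fit, probe):
    lines = [
        "# ocipipe run report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash()}",
        "",
        "## Tonotopic calibration",
        "",
        f"- cohort median slope: {median_slope:.3f} octaves/mm "
        f"(MAD {slope_mad:.3f}, n = {n_fits} hearing animals)",
        "",
        "## ICC activation by stimulation mode",
        "",
    ]
    if len(stc_df):
        by_mode = stc_df.groupby("condition", sort=False).agg(
            max_dprime=("max_dprime", "mean"), n_active=("n_active", "mean")
        )
        for mode, row in by_mode.iterrows():
            lines.append(
                f"- {mode}: mean max d' = {row.max_dprime:.2f}, "
                f"mean active electrodes = {row.n_active:.1f} / {probe.n_electrodes}"
            )
    lines += ["", "## Spread of excitation (achieved criteria only)", ""]
    if len(spread_df):
        ach = spread_df[spread_df["achieved"]]
        if len(ach):
            for (mode, crit), grp in ach.groupby(["condition", "criterion_dprime"]):
                lines.append(
                    f"- {mode} @ d'={crit}: {grp['span_octaves'].mean():.2f} octaves "
                    f"({grp['span_mm'].mean() * 1000:.0f} um in the ICC, n={len(grp)})"
                )
    lines += ["", "## Tonotopic place code", ""]
    if place_fit is not None:
        lines.append(
            f"- BE shift: {place_fit.slope_electrodes_per_mm:.2f} electrodes/mm "
            f"(r = {place_fit.pearson_r:.2f}, p = {place_fit.p_value:.2g}, "
            f"n = {place_fit.n_points})"
        )
    else:
        lines.append("- too few qualifying spatial tuning curves for a fit")
    (Path(outdir) / "report.md").write_text("\n".join(lines) + "\n")
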