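"""End-to-end orchestration: simulate → texture → model → report.

A single declarative config drives the whole analysis.  Outputs are
plain CSV/JSON tables stamped with the config hash and seed:

* ``records.csv`` — one TextureRecord per scan;
* ``table1.csv`` — per-parameter descriptives (mean, SD by phase) and
  posterior after/before ratios with 95 % credibility intervals;
* ``loo.json`` — the M0 vs M1 PSIS-LOO comparison;
* ``force_summary.csv`` — per-area peak-force statistics and the
  cut-vs-control comparison;
* ``fig4_pairs.csv`` — matched before/after values per location and
  parameter (the pairwise-scatter data);
* ``zooms.csv`` — per-sample marker S/N values and taxon calls;
* ``gof.csv`` — Mahalanobis goodness-of-fit distances vs F quantiles;
* ``run.json`` — config echo, hash, seed and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as mm
from .force import compare_force_groups, detect_contact_events, summarize_peak_forces
from .io import records_to_dataframe, write_records_csv
from .iso25178 import TextureSettings, compute_texture_record
from .preprocess import PairRejection, align_pair
from .surfaces import Phase, ScanMetadata, TextureRecord
from .synthetic import (
    StudyGenParams,
    SurfaceGenParams,
    WearParams,
    apply_eem_wear,
    generate_force_trace,
    generate_spectrum,
    generate_study,
    generate_surface,
    study_design,
)
from .zooms import assign_taxon, default_marker_db

__all__ = ["PipelineConfig", "run_pipeline", "fig4_pairs", "plot_pairs"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "model_level"  # or "surface_level"
    study: StudyGenParams = field(default_factory=lambda: StudyGenParams(drop_pairs=1))
    surface: SurfaceGenParams = field(default_factory=SurfaceGenParams)
    wear: WearParams = field(default_factory=WearParams)
    min_overlap: float = 0.25
    # (specimen, area, location) of a pair given a large lateral offset, or None
    inject_offset_pair: tuple[str, str, int] | None = None
    inject_offset_um: tuple[float, float] = (0.0, 0.0)
    # force stage
    force_events_per_sample: int = 50
    peak_mean: float = 8.12
    peak_sd: float = 1.21
    # zooms stage
    zooms_snr: float = 40.0
    zooms_markers_present: tuple[str, ...] = (
        "COL1a1 508-519",
        "COL1a2 978-990",
        "COL1a2 484-498",
    )
    # sampler
    chains: int = 4
    draws: int = 1000
    warmup: int = 2000
    thin: int = 8

    def hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def fig4_pairs(records: list[TextureRecord] | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched before/after table: one row per location and parameter.

    Returns ``(pairs, exclusions)``; unpaired records land in the
    exclusions table instead of silently disappearing.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_dataframe(records)
    rows = []
    excl = []
    grouped = df.groupby(["specimen", "area", "location"], sort=True)
    for (spec, area, loc), sub in grouped:
        phases = set(sub["phase"])
        if phases != {"before", "after"}:
            for _, r in sub.iterrows():
                excl.append(
                    {"specimen": spec, "area": area, "location": loc, "phase": r["phase"],
                     "reason": "unpaired"}
                )
            continue
        b = sub[sub["phase"] == "before"].iloc[0]
        a = sub[sub["phase"] == "after"].iloc[0]
        for par in mm.PARAMETERS:
            rows.append(
                {
                    "specimen": spec, "area": area, "location": int(loc), "parameter": par,
                    "before": float(b[par]), "after": float(a[par]),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(excl)


def plot_pairs(pairs: pd.DataFrame, axes=None):
    """Matched before/after scatterplots per parameter with identity lines."""
    import matplotlib.pyplot as plt

    params = list(dict.fromkeys(pairs["parameter"]))
    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(7, 6))
    for ax, par in zip(np.ravel(axes), params):
        sub = pairs[pairs["parameter"] == par]
        for area, color in (("cut", "#c8a400"), ("control", "#b03a2e")):
            pts = sub[sub["area"] == area]
            ax.scatter(pts["before"], pts["after"], s=14, color=color, label=area, alpha=0.8)
        lim = [min(sub["before"].min(), sub["after"].min()), max(sub["before"].max(), sub["after"].max())]
        ax.plot(lim, lim, color="0.6", lw=1)
        ax.set_title(par)
        ax.set_xlabel("before")
        ax.set_ylabel("after")
    np.ravel(axes)[0].legend(frameon=False, fontsize=8)
    return axes


def _simulate_records(config: PipelineConfig, seed: int, log: dict) -> list[TextureRecord]:
    if config.mode == "model_level":
        records, _ = generate_study(config.study, mode="model_level", seed=seed)
        log["pairs_removed_overlap"] = []
        return records

    # surface level: generate each pair, register it, reject minimal overlap
    metas = study_design(config.study)
    locations = sorted({m.pair_key for m in metas})
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    loc_seeds = dict(zip(locations, ss.spawn(len(locations) + 1)[1:]))
    spec_ids = sorted({m.specimen for m in metas})
    u_spec = {s: rng.normal() * config.study.specimen_sd[0] for s in spec_ids}
    settings = TextureSettings()
    records: list[TextureRecord] = []
    removed = []
    for key in locations:
        specimen, area, loc = key
        u_loc = rng.normal() * config.study.location_sd[0]
        scale = float(np.exp(u_spec[specimen] + u_loc))
        local = replace(config.surface, target_Sa=config.surface.target_Sa * scale)
        child = loc_seeds[key].spawn(3)
        base = generate_surface(local, child[0])
        noise_rng = np.random.default_rng(child[1])
        before = base.with_heights(
            base.heights + noise_rng.normal(scale=config.wear.remeasure_noise_sd, size=base.shape)
        )
        wear = config.wear
        known_offset = None
        if config.inject_offset_pair is not None and tuple(config.inject_offset_pair) == key:
            wear = replace(wear, lateral_offset=tuple(config.inject_offset_um))
            known_offset = tuple(config.inject_offset_um)  # offsets are manually defined
        after = apply_eem_wear(base, wear, child[2])
        result = align_pair(before, after, offset=known_offset, min_overlap=config.min_overlap)
        if isinstance(result, PairRejection):
            removed.append(
                {"specimen": specimen, "area": area, "location": loc,
                 "overlap_fraction": result.overlap_fraction}
            )
            continue
        records.append(
            compute_texture_record(result.before, ScanMetadata(specimen, area, loc, Phase.BEFORE), settings)
        )
        records.append(
            compute_texture_record(result.after, ScanMetadata(specimen, area, loc, Phase.AFTER), settings)
        )
    log["pairs_removed_overlap"] = removed
    return records


def _force_stage(config: PipelineConfig, seed: int, outdir: Path, log: dict) -> None:
    metas = study_design(config.study)
    samples = sorted({(m.specimen, m.area.value) for m in metas})
    ss = np.random.SeedSequence(seed).spawn(len(samples))
    rows = []
    per_specimen_area: dict[str, list[float]] = {"cut": [], "control": []}
    for (specimen, area), s in zip(samples, ss):
        trace = generate_force_trace(
            config.force_events_per_sample, config.peak_mean, config.peak_sd, seed=s
        )
        events = detect_contact_events(trace)
        summ = summarize_peak_forces(events, duration=trace.duration)
        rows.append({"specimen": specimen, "area": area, **summ})
        per_specimen_area[area].append(summ["mean"])
    df = pd.DataFrame(rows)
    comparison = compare_force_groups(
        {"cut": np.array(per_specimen_area["cut"]), "control": np.array(per_specimen_area["control"])}
    )
    df.to_csv(outdir / "force_summary.csv", index=False)
    log["force"] = {
        "n_samples": len(rows),
        "overall_mean_N": float(df["mean"].mean()),
        "comparison": comparison,
    }


def _zooms_stage(config: PipelineConfig, seed: int, outdir: Path, log: dict) -> None:
    db = default_marker_db()
    present = [m for m in db if m.name in config.zooms_markers_present]
    metas = study_design(config.study)
    samples = sorted({(m.specimen, m.area.value) for m in metas})
    ss = np.random.SeedSequence(seed).spawn(len(samples))
    rows = []
    for (specimen, area), s in zip(samples, ss):
        spec = generate_spectrum(present, snr=config.zooms_snr, seed=s, label=f"{specimen}-{area}")
        call = assign_taxon(spec, db)
        row = {"specimen": specimen, "area": area, "taxa": "/".join(sorted(call.taxa))}
        for m in db:
            row[f"snr {m.name}"] = round(call.snr.get(m.name, 0.0), 2)
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "zooms.csv", index=False)
    log["zooms"] = {"n_samples": len(rows)}


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Run the full analysis; returns the run log (also written to run.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.hash(), "seed": seed, "stages": []}
    ss = np.random.SeedSequence(seed)
    s_sim, s_force, s_zooms, s_fit = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    try:
        records = _simulate_records(config, s_sim, log)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    write_records_csv(records, outdir / "records.csv")
    log["stages"].append({"stage": "simulate", "n_records": len(records)})

    df = records_to_dataframe(records)
    complete = df[np.isfinite(df[list(mm.PARAMETERS)]).all(axis=1)]
    dropped_incomplete = len(df) - len(complete)

    pairs, excl = fig4_pairs(complete)
    pairs.to_csv(outdir / "fig4_pairs.csv", index=False)
    if not excl.empty:
        excl.to_csv(outdir / "fig4_exclusions.csv", index=False)
    log["stages"].append({"stage": "pairs", "n_pairs": int(len(pairs) / 4) if len(pairs) else 0})

    _force_stage(config, s_force, outdir, log)
    log["stages"].append({"stage": "force"})
    _zooms_stage(config, s_zooms, outdir, log)
    log["stages"].append({"stage": "zooms"})

    try:
        fit1 = mm.SurfaceTextureModel.from_dataframe(complete, "M1").fit(
            chains=config.chains, draws=config.draws, warmup=config.warmup,
            thin=config.thin, seed=s_fit,
        )
        fit0 = mm.SurfaceTextureModel.from_dataframe(complete, "M0").fit(
            chains=config.chains, draws=config.draws, warmup=config.warmup,
            thin=config.thin, seed=s_fit + 1,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    loo = mm.compare_loo(fit0, fit1)
    (outdir / "loo.json").write_text(json.dumps(_jsonable(loo), indent=2))

    desc = mm.descriptive_table(complete)
    ratios = fit1.posterior_ratios("erasing")
    table1 = []
    for par in mm.PARAMETERS:
        b = desc[(desc["parameter"] == par) & (desc["phase"] == "before")].iloc[0]
        a = desc[(desc["parameter"] == par) & (desc["phase"] == "after")].iloc[0]
        r = ratios.loc[par]
        table1.append(
            {
                "parameter": par,
                "before_mean": round(b["mean"], 2), "before_sd": round(b["sd"], 2),
                "after_mean": round(a["mean"], 2), "after_sd": round(a["sd"], 2),
                "ratio_q2.5": round(r["q2.5"], 2), "ratio_median": round(r["median"], 2),
                "ratio_q97.5": round(r["q97.5"], 2),
            }
        )
    pd.DataFrame(table1).to_csv(outdir / "table1.csv", index=False)
    gof = fit1.gof_mahalanobis()
    gof.to_csv(outdir / "gof.csv", index=False)
    log["stages"].append(
        {
            "stage": "fit",
            "n_scans": int(complete.shape[0]),
            "dropped_incomplete": dropped_incomplete,
            "max_rhat": fit1.max_rhat,
            "loo_preferred": loo["preferred"],
            "qq_slope": gof.attrs["qq_slope"],
        }
    )
    (outdir / "run.json").write_text(json.dumps(_jsonable(log), indent=2))
    return log
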