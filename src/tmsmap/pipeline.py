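"""End-to-end orchestration: simulate → process → map → overlap → summarize.

Each stage reads and writes plain-text artifacts (CSV, ASCII grids, JSON)
so it can be re-run independently, and the whole pipeline is deterministic
under a fixed seed.  ``run_pipeline`` chains the stages into one artifact
directory with a run manifest recording every option and library version.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emg import process_trial
from .mapping import (
    MotorMap,
    interpolate_map,
    merge_sites,
    project_to_plane,
    write_ascii_grid,
)
from .overlap import overlap_report
from .summary import (
    condition_summary,
    normalize_within_subject,
    od_category_distribution,
    to_long_table,
)
from .synth import SynthConfig, StimTrial, simulate_experiment, write_dataset

__all__ = [
    "MapOptions",
    "RunConfig",
    "trials_to_meps",
    "process_dataset",
    "build_maps",
    "overlaps_from_maps",
    "analyze_trials",
    "run_pipeline",
]


@dataclass
class MapOptions:
    """Map-construction and overlap options shared by all stages."""

    resolution_mm: float = 1.0
    threshold_uv: float = 50.0
    merge_radius_mm: float = 3.0
    margin_mm: float = 10.0
    emd_bin_mm: float = 4.0  # EMD solved on blocks of about this size
    compute_emd: bool = True

    def emd_coarsen(self) -> int:
        return max(1, int(round(self.emd_bin_mm / self.resolution_mm)))


@dataclass
class RunConfig:
    """Full pipeline configuration (JSON-serialisable)."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    mapping: MapOptions = field(default_factory=MapOptions)
    seed: int | None = None  # overrides synth.seed when given

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        synth_kw = raw.get("synth", {})
        muscles = synth_kw.pop("muscles", None)
        cfg = SynthConfig(**synth_kw)
        if muscles is not None:
            from .synth import ExcitabilityField

            cfg.muscles = {
                name: ExcitabilityField(
                    center=tuple(spec["center"]),
                    sigma=spec["sigma"],
                    peak_amp=spec["peak_amp"],
                    **(
                        {"intensity_gain": spec["intensity_gain"]}
                        if "intensity_gain" in spec
                        else {}
                    ),
                )
                for name, spec in muscles.items()
            }
        return cls(
            synth=cfg,
            mapping=MapOptions(**raw.get("mapping", {})),
            seed=raw.get("seed"),
        )


# ---------------------------------------------------------------------------
# process stage
# ---------------------------------------------------------------------------


def trials_to_meps(trials: list[StimTrial]) -> pd.DataFrame:
    """Extract and screen MEPs from in-memory trials (one row per muscle)."""
    rows = []
    for tr in trials:
        for muscle in tr.muscles:
            rec = process_trial(tr.traces[muscle], tr.trigger_index, tr.sample_rate)
            rows.append(
                {
                    "subject": tr.subject_id,
                    "muscle": muscle,
                    "intensity_pct_rmt": tr.intensity_pct_rmt,
                    "site_id": tr.site_id,
                    "trial_id": tr.trial_id,
                    "amplitude_uV": rec.amplitude_uv,
                    "latency_ms": rec.latency_ms,
                    "accepted": rec.accepted,
                    "reason": rec.reject_reason.value,
                }
            )
    return pd.DataFrame(rows)


def process_dataset(data_dir) -> pd.DataFrame:
    """Read a written dataset (sites.csv + trace CSVs) and extract MEPs."""
    data_dir = Path(data_dir)
    sites = pd.read_csv(data_dir / "sites.csv")
    rows = []
    for _, r in sites.iterrows():
        df = pd.read_csv(data_dir / r["trace_file"])
        trigger = int(r["trigger_index"])
        fs = float(r["sample_rate_hz"])
        for muscle in (c for c in df.columns if c != "time_ms"):
            rec = process_trial(df[muscle].to_numpy(), trigger, fs)
            rows.append(
                {
                    "subject": r["subject"],
                    "muscle": muscle,
                    "intensity_pct_rmt": r["intensity_pct_rmt"],
                    "site_id": r["site_id"],
                    "trial_id": r["trial_id"],
                    "amplitude_uV": rec.amplitude_uv,
                    "latency_ms": rec.latency_ms,
                    "accepted": rec.accepted,
                    "reason": rec.reject_reason.value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# map stage
# ---------------------------------------------------------------------------


def build_maps(
    meps: pd.DataFrame, sites: pd.DataFrame, opts: MapOptions
) -> dict[tuple[str, float], dict[str, MotorMap]]:
    """Construct co-registered per-muscle maps for every subject x intensity.

    For each subject x intensity the 3-D coil coordinates are projected onto
    their least-squares plane once, and all muscle maps share one grid
    geometry (site extent + margin), so they can be intersected cellwise.
    Sites whose trials were all rejected are dropped from that muscle's map.
    """
    site_coords = (
        sites.groupby(["subject", "intensity_pct_rmt", "site_id"])[
            ["x_mm", "y_mm", "z_mm"]
        ]
        .first()
        .reset_index()
    )
    out: dict[tuple[str, float], dict[str, MotorMap]] = {}
    for (subject, intensity), sc in site_coords.groupby(
        ["subject", "intensity_pct_rmt"]
    ):
        coords2d, _ = project_to_plane(sc[["x_mm", "y_mm", "z_mm"]].to_numpy())
        pos = dict(zip(sc["site_id"], coords2d))
        xmin, ymin = coords2d.min(axis=0) - opts.margin_mm
        xmax, ymax = coords2d.max(axis=0) + opts.margin_mm
        extent = (float(xmin), float(xmax), float(ymin), float(ymax))

        sel = meps[
            (meps["subject"] == subject)
            & (meps["intensity_pct_rmt"] == intensity)
            & meps["accepted"]
        ]
        muscle_maps: dict[str, MotorMap] = {}
        for muscle, grp in sel.groupby("muscle"):
            med = grp.groupby("site_id")["amplitude_uV"].median()
            pts = np.array([pos[s] for s in med.index])
            merged_pts, merged_amp = merge_sites(
                pts, med.to_numpy(), opts.merge_radius_mm
            )
            muscle_maps[muscle] = interpolate_map(
                merged_pts,
                merged_amp,
                resolution_mm=opts.resolution_mm,
                extent=extent,
                muscle=muscle,
                intensity=str(intensity),
            )
        out[(subject, float(intensity))] = muscle_maps
    return out


# ---------------------------------------------------------------------------
# overlap stage
# ---------------------------------------------------------------------------


def overlaps_from_maps(
    maps: dict[tuple[str, float], dict[str, MotorMap]], opts: MapOptions
) -> pd.DataFrame:
    frames = []
    for (subject, intensity), muscle_maps in maps.items():
        frames.append(
            overlap_report(
                muscle_maps,
                threshold_uv=opts.threshold_uv,
                intensity=str(intensity),
                subject=subject,
                emd_coarsen=opts.emd_coarsen(),
                compute_emd=opts.compute_emd,
            )
        )
    return pd.concat(frames, ignore_index=True)


def analyze_trials(
    trials: list[StimTrial], sites: pd.DataFrame, opts: MapOptions
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """In-memory process → map → overlap; returns (meps, maps, overlaps)."""
    meps = trials_to_meps(trials)
    maps = build_maps(meps, sites, opts)
    overlaps = overlaps_from_maps(maps, opts)
    return meps, maps, overlaps


def _sites_frame(trials: list[StimTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [t.subject_id for t in trials],
            "intensity_pct_rmt": [t.intensity_pct_rmt for t in trials],
            "site_id": [t.site_id for t in trials],
            "x_mm": [t.coil_coord[0] for t in trials],
            "y_mm": [t.coil_coord[1] for t in trials],
            "z_mm": [t.coil_coord[2] for t in trials],
        }
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage, writing all artifacts plus a run manifest.

    Layout::

        out_dir/dataset/           sites.csv, traces/, ground_truth.json
        out_dir/meps.csv
        out_dir/maps/              <subject>_i<intensity>_<muscle>.asc (+ .json)
        out_dir/overlaps.csv
        out_dir/summary_long.csv   normalised long-format parameter table
        out_dir/summary_distribution.csv
        out_dir/summary_means.csv
        out_dir/manifest.json
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config
    if cfg.seed is not None:
        cfg = dataclasses.replace(cfg, synth=dataclasses.replace(cfg.synth, seed=cfg.seed))
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    trials, truth = simulate_experiment(cfg.synth, threshold_uv=cfg.mapping.threshold_uv)
    write_dataset(trials, truth, out_dir / "dataset")
    timings["simulate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    meps = process_dataset(out_dir / "dataset")
    meps.to_csv(out_dir / "meps.csv", index=False)
    timings["process_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sites = pd.read_csv(out_dir / "dataset" / "sites.csv")
    maps = build_maps(meps, sites, cfg.mapping)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for (subject, intensity), mm in maps.items():
        for muscle, m in mm.items():
            write_ascii_grid(m, maps_dir / f"{subject}_i{int(intensity)}_{muscle}.asc")
    timings["map_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    overlaps = overlaps_from_maps(maps, cfg.mapping)
    overlaps.to_csv(out_dir / "overlaps.csv", index=False)
    timings["overlap_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    long = normalize_within_subject(to_long_table(overlaps))
    long.to_csv(out_dir / "summary_long.csv", index=False)
    od_category_distribution(long).to_csv(
        out_dir / "summary_distribution.csv", index=False
    )
    condition_summary(long).to_csv(out_dir / "summary_means.csv", index=False)
    timings["summary_s"] = time.perf_counter() - t0

    manifest = {
        "tmsmap_version": __version__,
        "numpy": np.__version__,
        "scipy": __import__("scipy").__version__,
        "pandas": pd.__version__,
        "seed": cfg.synth.seed,
        "synth": _jsonable(dataclasses.asdict(cfg.synth)),
        "mapping": dataclasses.asdict(cfg.mapping),
        "n_trials": len(trials),
        "n_mep_rows": int(len(meps)),
        "n_rejected_rows": int((~meps["accepted"]).sum()),
        "n_overlap_records": int(len(overlaps)),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
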