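"""Synthetic nTMS motor-mapping experiments with known ground truth.

Real mapping sessions deliver short TMS pulse trains over a pseudo-random
grid of coil positions centred on a muscle's hotspot while surface EMG is
recorded from several muscles at once.  No public recordings exist for this
protocol, so this module emulates it: each muscle's cortical representation
is modelled as an isotropic 2-D Gaussian *excitability field* (peak MEP
amplitude at the field centre, exponential fall-off with distance), and each
simulated pulse produces one EMG trace per muscle containing baseline noise
plus a biphasic MEP whose peak-to-peak amplitude equals the field value at
the stimulated site.

Because the fields are analytic, the true suprathreshold areas and the true
overlap degree between any two or three muscle representations are known
exactly, which makes every downstream stage (MEP extraction, map
interpolation, overlap metrics) testable by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExcitabilityField",
    "SynthConfig",
    "StimTrial",
    "GroundTruth",
    "generate_grid",
    "simulate_trial",
    "simulate_experiment",
    "true_area_od",
    "true_area_od_three",
    "write_dataset",
    "load_trial_csv",
]

#: peak-to-peak amplitudes below this floor emit no MEP deflection at all,
#: mimicking absent responses at the map fringe.
AMPLITUDE_FLOOR_UV = 10.0

#: reference stimulation intensity (% rMT) at which a field's gain is 1.
REFERENCE_INTENSITY_PCT = 110.0


@dataclass(frozen=True)
class ExcitabilityField:
    """Gaussian model of one muscle's cortical motor representation.

    ``amplitude(x) = peak_amp * gain * exp(-|x - center|^2 / (2 sigma^2))``
    where ``gain`` is 1 at the reference intensity (110 % rMT) and
    ``intensity_gain`` per additional +10 % rMT step, reflecting the larger
    cortical region recruited by stronger stimuli.

    Parameters
    ----------
    center : (float, float)
        Field centre in the map plane, mm.
    sigma : float
        Spatial spread, mm (> 0).
    peak_amp : float
        Peak-to-peak MEP amplitude at the centre at reference intensity, µV.
    intensity_gain : float
        Multiplicative amplitude gain per +10 % rMT above reference (>= 1).
    """

    center: tuple[float, float]
    sigma: float
    peak_amp: float
    intensity_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.peak_amp <= 0:
            raise ValueError(f"peak_amp must be > 0, got {self.peak_amp}")
        if self.intensity_gain < 1:
            raise ValueError(
                f"intensity_gain must be >= 1, got {self.intensity_gain}"
            )

    def gain_at(self, intensity_pct_rmt: float) -> float:
        """Amplitude gain at a stimulation intensity given in % rMT."""
        steps = (intensity_pct_rmt - REFERENCE_INTENSITY_PCT) / 10.0
        return float(self.intensity_gain**steps)

    def amplitude(self, xy, intensity_pct_rmt: float = REFERENCE_INTENSITY_PCT):
        """Evoked peak-to-peak MEP amplitude (µV) at map-plane point(s) ``xy``."""
        xy = np.asarray(xy, dtype=float)
        d2 = np.sum((xy - np.asarray(self.center)) ** 2, axis=-1)
        return (
            self.peak_amp
            * self.gain_at(intensity_pct_rmt)
            * np.exp(-d2 / (2.0 * self.sigma**2))
        )

    def suprathreshold_radius(
        self, threshold: float, intensity_pct_rmt: float = REFERENCE_INTENSITY_PCT
    ) -> float:
        """Radius (mm) of the disc where amplitude > threshold (0 if none)."""
        peak = self.peak_amp * self.gain_at(intensity_pct_rmt)
        if peak <= threshold:
            return 0.0
        return self.sigma * math.sqrt(2.0 * math.log(peak / threshold))


def _default_fields() -> dict[str, ExcitabilityField]:
    # Distinct but heavily overlapping representations of one forearm (FCR)
    # and two intrinsic hand muscles (FPB thenar, ADM hypothenar).  Centres
    # sit a few mm apart on the motor knob; spreads of 8-9 mm give 50 µV
    # map areas of ~9-14 cm^2 and medium-to-high pairwise overlap degrees,
    # and make the representations resolvable by a 20-site grid at ~14.5 mm
    # spacing — the regime in which the emulated protocol operates.
    return {
        "FCR": ExcitabilityField(center=(0.0, 0.0), sigma=9.0, peak_amp=420.0),
        "FPB": ExcitabilityField(center=(8.0, 4.5), sigma=8.0, peak_amp=460.0),
        "ADM": ExcitabilityField(center=(4.0, -7.5), sigma=8.5, peak_amp=380.0),
    }


@dataclass
class SynthConfig:
    """Study-design parameters of a simulated mapping experiment.

    Defaults mirror the protocol this package analyses: a 20-site
    pseudo-random-walk grid with ~14.5 ± 3.6 mm site spacing, 3 pulses per
    site, stimulation at 110 % and 120 % of the resting motor threshold, EMG
    sampled at 3.5 kHz, MEP latency ~20 ms, and a 12-subject cohort.
    """

    n_subjects: int = 12
    n_sites: int = 20
    spacing_mean: float = 14.5
    spacing_sd: float = 3.6
    trials_per_site: int = 3
    intensities: tuple[float, ...] = (110.0, 120.0)
    muscles: dict[str, ExcitabilityField] = field(default_factory=_default_fields)
    noise_sd: float = 3.0
    artifact_rate: float = 0.005
    mep_latency_ms: float = 20.0
    sample_rate: float = 3500.0
    rmt_pct_mso: float = 45.0
    subject_jitter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sites", "trials_per_site"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.spacing_mean <= 0:
            raise ValueError("spacing_mean must be > 0")
        if self.spacing_sd < 0:
            raise ValueError("spacing_sd must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.intensities) < 1:
            raise ValueError("at least one intensity required")
        if len(self.muscles) < 1:
            raise ValueError("at least one muscle field required")


@dataclass
class StimTrial:
    """One TMS pulse: coil coordinate plus one EMG trace per muscle.

    Traces cover >= 300 ms before and >= 60 ms after the trigger so that both
    the pre-activation check and the MEP analysis window fit inside them.
    """

    subject_id: str
    site_id: int
    trial_id: int
    coil_coord: np.ndarray  # (3,) mm
    intensity_pct_rmt: float
    intensity_pct_mso: float
    muscles: tuple[str, ...]
    traces: dict[str, np.ndarray]  # µV, one array per muscle
    trigger_index: int
    sample_rate: float

    def __post_init__(self) -> None:
        self.coil_coord = np.asarray(self.coil_coord, dtype=float)
        if not np.all(np.isfinite(self.coil_coord)):
            raise ValueError("coil coordinates must be finite")
        n = {len(v) for v in self.traces.values()}
        if len(n) != 1:
            raise ValueError("all muscle traces must share one length")
        if not 0 <= self.trigger_index < n.pop():
            raise ValueError("trigger_index outside trace")


@dataclass
class GroundTruth:
    """Per-subject generative truth for parameter-recovery tests."""

    fields: dict[str, dict[str, ExcitabilityField]]  # subject -> muscle -> field
    area_od: pd.DataFrame  # subject, intensity, muscles, true_od_pct
    threshold_uv: float


# ---------------------------------------------------------------------------
# grid generation
# ---------------------------------------------------------------------------

#: walk extent: a disc of this radius has the same area as the 6 x 6 cm
#: coverage region conventionally mapped by the pseudo-random-walk protocol,
#: which is also the area that 20 sites at ~14.5 mm spacing tile.
MAX_HOTSPOT_DISTANCE_MM = 34.0


def generate_grid(hotspot, cfg: SynthConfig, rng_seed: int | None = None) -> np.ndarray:
    """Pseudo-random-walk grid of stimulation sites around the hotspot.

    Starting at the hotspot, each subsequent site is one jump away from the
    previous one: jump length drawn from N(spacing_mean, spacing_sd) and
    direction uniform on the circle.  A candidate is resampled if it falls
    closer than ``spacing_mean - spacing_sd`` to an existing site or more
    than 34 mm from the hotspot; the separation rule is what makes the
    realised nearest-neighbour spacing match the configured mean ± sd
    statistics instead of collapsing as the walk revisits covered ground.
    If a walk position gets boxed in, it restarts from a random earlier
    site.

    Returns an (n_sites, 2) array of map-plane coordinates (mm); the first
    site is exactly the hotspot.
    """
    if cfg.spacing_mean <= 0:
        raise ValueError("spacing_mean must be > 0")
    min_sep = max(cfg.spacing_mean - cfg.spacing_sd, 0.0)
    hotspot = np.asarray(hotspot, dtype=float)[:2]
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    sites = [hotspot.copy()]
    current = hotspot.copy()
    while len(sites) < cfg.n_sites:
        for attempt in range(2000):
            step = rng.normal(cfg.spacing_mean, cfg.spacing_sd)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = current + abs(step) * np.array([np.cos(theta), np.sin(theta)])
            far_enough = all(np.linalg.norm(cand - s) >= min_sep for s in sites)
            if far_enough and np.linalg.norm(cand - hotspot) <= MAX_HOTSPOT_DISTANCE_MM:
                break
            if (attempt + 1) % 50 == 0:  # boxed in: hop to a random earlier site
                current = sites[int(rng.integers(len(sites)))]
        else:  # pragma: no cover - requires pathological config
            raise RuntimeError("could not place a grid site; config too tight")
        sites.append(cand)
        current = cand
    return np.asarray(sites)


# ---------------------------------------------------------------------------
# single-trial EMG synthesis
# ---------------------------------------------------------------------------

PRE_TRIGGER_MS = 400.0
POST_TRIGGER_MS = 100.0
MEP_DURATION_MS = 15.0


def _mep_waveform(n_samples: int, sample_rate: float, latency_ms: float,
                  amplitude_uv: float, trigger_index: int) -> np.ndarray:
    """One-cycle biphasic sine of given peak-to-peak amplitude at latency."""
    wave = np.zeros(n_samples)
    onset = trigger_index + int(round(latency_ms * sample_rate / 1000.0))
    n_mep = int(round(MEP_DURATION_MS * sample_rate / 1000.0))
    t = np.arange(n_mep) / max(n_mep - 1, 1)
    segment = np.sin(2.0 * np.pi * t)
    # rescale so the SAMPLED peak-to-peak equals amplitude_uv exactly
    segment *= amplitude_uv / (segment.max() - segment.min())
    end = min(onset + n_mep, n_samples)
    wave[onset:end] = segment[: end - onset]
    return wave


def simulate_trial(
    site,
    fields: dict[str, ExcitabilityField],
    intensity_pct_rmt: float,
    noise_sd: float,
    artifact: bool = False,
    rng_seed: int | np.random.Generator | None = None,
    *,
    sample_rate: float = 3500.0,
    mep_latency_ms: float = 20.0,
    subject_id: str = "S00",
    site_id: int = 0,
    trial_id: int = 0,
    rmt_pct_mso: float = 45.0,
    coil_coord=None,
) -> StimTrial:
    """Forward-model one TMS pulse into per-muscle EMG traces.

    Each trace is Gaussian baseline noise plus a biphasic MEP at the given
    latency whose peak-to-peak amplitude equals the muscle field's value at
    ``site``; amplitudes below the 10 µV floor produce no deflection.  With
    ``artifact=True`` a >20 µV excursion is injected in the 300 ms
    pre-trigger window so that the pre-activation check must reject the
    trial.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    site = np.asarray(site, dtype=float)[:2]
    n_pre = int(round(PRE_TRIGGER_MS * sample_rate / 1000.0))
    n_post = int(round(POST_TRIGGER_MS * sample_rate / 1000.0))
    n_samples = n_pre + n_post
    trigger_index = n_pre

    traces: dict[str, np.ndarray] = {}
    for name, fld in fields.items():
        amp = float(fld.amplitude(site, intensity_pct_rmt))
        trace = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
        if amp >= AMPLITUDE_FLOOR_UV:
            trace += _mep_waveform(n_samples, sample_rate, mep_latency_ms, amp, trigger_index)
        if artifact:
            # burst of muscle pre-activation 150 ms before the pulse
            a_onset = trigger_index - int(round(0.150 * sample_rate))
            n_art = int(round(0.030 * sample_rate))
            t = np.arange(n_art) / max(n_art - 1, 1)
            trace[a_onset : a_onset + n_art] += 50.0 * np.sin(2.0 * np.pi * 2 * t)
        traces[name] = trace

    if coil_coord is None:
        coil_coord = np.array([site[0], site[1], 0.0])
    return StimTrial(
        subject_id=subject_id,
        site_id=site_id,
        trial_id=trial_id,
        coil_coord=np.asarray(coil_coord, dtype=float),
        intensity_pct_rmt=intensity_pct_rmt,
        intensity_pct_mso=rmt_pct_mso * intensity_pct_rmt / 100.0,
        muscles=tuple(fields),
        traces=traces,
        trigger_index=trigger_index,
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# ground-truth overlap degree
# ---------------------------------------------------------------------------


def true_area_od(
    field_a: ExcitabilityField,
    field_b: ExcitabilityField,
    threshold: float = 50.0,
    resolution: float = 0.1,
    intensity_pct_rmt: float = REFERENCE_INTENSITY_PCT,
) -> float:
    """True area overlap degree (%) of two analytic fields.

    Evaluates both fields on a dense grid (resolution <= 0.5 mm), thresholds
    them, and applies the two-map overlap-degree formula
    ``X12*100/(X1+X2-X12)`` to the counted cells.
    """
    return _grid_od([field_a, field_b], threshold, resolution, intensity_pct_rmt)


def true_area_od_three(
    field_a: ExcitabilityField,
    field_b: ExcitabilityField,
    field_c: ExcitabilityField,
    threshold: float = 50.0,
    resolution: float = 0.1,
    intensity_pct_rmt: float = REFERENCE_INTENSITY_PCT,
) -> float:
    """True area overlap degree (%) of three analytic fields (triple form)."""
    return _grid_od([field_a, field_b, field_c], threshold, resolution, intensity_pct_rmt)


def _grid_od(fields, threshold, resolution, intensity_pct_rmt) -> float:
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if resolution > 0.5:
        raise ValueError("resolution must be <= 0.5 mm for the dense oracle")
    radii = [f.suprathreshold_radius(threshold, intensity_pct_rmt) for f in fields]
    centers = np.asarray([f.center for f in fields])
    lo = (centers - np.asarray(radii)[:, None]).min(axis=0) - resolution
    hi = (centers + np.asarray(radii)[:, None]).max(axis=0) + resolution
    x = np.arange(lo[0], hi[0], resolution)
    y = np.arange(lo[1], hi[1], resolution)
    xx, yy = np.meshgrid(x, y)
    pts = np.stack([xx, yy], axis=-1)
    masks = [f.amplitude(pts, intensity_pct_rmt) > threshold for f in fields]
    inter = np.logical_and.reduce(masks).sum()
    union = np.logical_or.reduce(masks).sum()
    if union == 0:
        return float("nan")
    return 100.0 * float(inter) / float(union)


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------


def _subject_fields(
    base: dict[str, ExcitabilityField], rng: np.random.Generator, jitter: bool
) -> dict[str, ExcitabilityField]:
    """Biological between-subject variability around the cohort-level fields."""
    if not jitter:
        return dict(base)
    out = {}
    for name, f in base.items():
        out[name] = ExcitabilityField(
            center=(
                f.center[0] + rng.normal(0.0, 1.5),
                f.center[1] + rng.normal(0.0, 1.5),
            ),
            sigma=f.sigma * rng.uniform(0.9, 1.1),
            peak_amp=f.peak_amp * rng.uniform(0.8, 1.2),
            intensity_gain=f.intensity_gain,
        )
    return out


def simulate_experiment(
    cfg: SynthConfig, threshold_uv: float = 50.0
) -> tuple[list[StimTrial], GroundTruth]:
    """Simulate a full cohort and return (trials, ground truth).

    For each subject one pseudo-random-walk grid is generated around the
    composite hotspot (mean of that subject's field centres) and reused at
    every stimulation intensity, giving
    ``n_subjects x len(intensities) x n_sites x trials_per_site`` pulses,
    each with one trace per muscle.  The ground truth records every field and
    the true pairwise/triple area OD at each intensity at ``threshold_uv``.
    """
    rng = np.random.default_rng(cfg.seed)
    trials: list[StimTrial] = []
    fields_by_subject: dict[str, dict[str, ExcitabilityField]] = {}
    od_rows = []
    muscle_names = list(cfg.muscles)

    for si in range(cfg.n_subjects):
        subject = f"S{si + 1:02d}"
        fields = _subject_fields(cfg.muscles, rng, cfg.subject_jitter)
        fields_by_subject[subject] = fields
        hotspot = np.mean([f.center for f in fields.values()], axis=0)
        grid_seed = int(rng.integers(0, 2**31 - 1))
        sites = generate_grid(hotspot, cfg, rng_seed=grid_seed)

        for intensity in cfg.intensities:
            for a, b in _pairs(muscle_names):
                od_rows.append(
                    {
                        "subject": subject,
                        "intensity_pct_rmt": intensity,
                        "muscles": f"{a}&{b}",
                        "true_od_pct": true_area_od(
                            fields[a], fields[b], threshold_uv, 0.1, intensity
                        ),
                    }
                )
            if len(muscle_names) >= 3:
                a, b, c = muscle_names[:3]
                od_rows.append(
                    {
                        "subject": subject,
                        "intensity_pct_rmt": intensity,
                        "muscles": f"{a}&{b}&{c}",
                        "true_od_pct": true_area_od_three(
                            fields[a], fields[b], fields[c], threshold_uv, 0.1, intensity
                        ),
                    }
                )
            for site_id, site in enumerate(sites):
                for trial_id in range(cfg.trials_per_site):
                    artifact = bool(rng.random() < cfg.artifact_rate)
                    trials.append(
                        simulate_trial(
                            site,
                            fields,
                            intensity,
                            cfg.noise_sd,
                            artifact=artifact,
                            rng_seed=rng,
                            sample_rate=cfg.sample_rate,
                            mep_latency_ms=cfg.mep_latency_ms,
                            subject_id=subject,
                            site_id=site_id,
                            trial_id=trial_id,
                            rmt_pct_mso=cfg.rmt_pct_mso,
                        )
                    )

    truth = GroundTruth(
        fields=fields_by_subject,
        area_od=pd.DataFrame(od_rows),
        threshold_uv=threshold_uv,
    )
    return trials, truth


def _pairs(names):
    return [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]


# ---------------------------------------------------------------------------
# on-disk dataset format
# ---------------------------------------------------------------------------


def write_dataset(trials: list[StimTrial], truth: GroundTruth, out_dir) -> Path:
    """Write a simulated dataset: site log CSV, per-trial trace CSVs, truth JSON.

    Layout::

        out_dir/sites.csv                       one row per pulse
        out_dir/traces/<subject>_i<int>_s<site>_t<trial>.csv
        out_dir/ground_truth.json
    """
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        fname = _trace_filename(tr)
        rows.append(
            {
                "subject": tr.subject_id,
                "muscle_target": "ALL",
                "intensity_pct_rmt": tr.intensity_pct_rmt,
                "intensity_pct_mso": tr.intensity_pct_mso,
                "site_id": tr.site_id,
                "trial_id": tr.trial_id,
                "x_mm": tr.coil_coord[0],
                "y_mm": tr.coil_coord[1],
                "z_mm": tr.coil_coord[2],
                "trigger_index": tr.trigger_index,
                "sample_rate_hz": tr.sample_rate,
                "trace_file": f"traces/{fname}",
            }
        )
        n = len(next(iter(tr.traces.values())))
        time_ms = (np.arange(n) - tr.trigger_index) * 1000.0 / tr.sample_rate
        data = np.column_stack([time_ms] + [tr.traces[m] for m in tr.muscles])
        header = ",".join(["time_ms"] + list(tr.muscles))
        np.savetxt(
            out_dir / "traces" / fname,
            data,
            delimiter=",",
            header=header,
            comments="",
            fmt="%.4f",
        )
    pd.DataFrame(rows).to_csv(out_dir / "sites.csv", index=False)

    gt = {
        "threshold_uv": truth.threshold_uv,
        "fields": {
            subj: {m: dataclasses.asdict(f) for m, f in fs.items()}
            for subj, fs in truth.fields.items()
        },
        "area_od": truth.area_od.to_dict(orient="records"),
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    return out_dir


def _trace_filename(tr: StimTrial) -> str:
    return (
        f"{tr.subject_id}_i{int(round(tr.intensity_pct_rmt))}"
        f"_s{tr.site_id:02d}_t{tr.trial_id}.csv"
    )


def load_trial_csv(path) -> tuple[np.ndarray, dict[str, np.ndarray], int, float]:
    """Read one trace CSV back: (time_ms, traces by muscle, trigger index, fs)."""
    df = pd.read_csv(path)
    time_ms = df["time_ms"].to_numpy()
    traces = {c: df[c].to_numpy() for c in df.columns if c != "time_ms"}
    dt = np.median(np.diff(time_ms))
    fs = 1000.0 / dt
    trigger_index = int(np.argmin(np.abs(time_ms)))
    return time_ms, traces, trigger_index, fs
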