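"""Build an interpolated motor map and compute its size and location metrics.

Simulates one subject's stimulation grid, processes all pulses of one
muscle into per-site median amplitudes, merges closely spaced sites,
projects coil coordinates onto the best-fit plane, interpolates a regular
1 mm map and reports area (mm²), volume (mm²·µV) and centroid (mm).
"""

import numpy as np

import tmsmap as tm
from tmsmap.emg import process_trial

cfg = tm.SynthConfig(n_subjects=1, seed=8)
trials, truth = tm.simulate_experiment(cfg)
muscle = "FCR"
sel = [t for t in trials if t.intensity_pct_rmt == 110.0]

# per-site median of the accepted MEP amplitudes
by_site: dict[int, list[float]] = {}
coords: dict[int, np.ndarray] = {}
for t in sel:
    rec = process_trial(t.traces[muscle], t.trigger_index, t.sample_rate)
    if rec.accepted:
        by_site.setdefault(t.site_id, []).append(rec.amplitude_uv)
        coords[t.site_id] = t.coil_coord
site_ids = sorted(by_site)
amps = np.array([tm.aggregate_site(by_site[s]) for s in site_ids])

coords2d, plane = tm.project_to_plane(np.array([coords[s] for s in site_ids]))
merged_xy, merged_amp = tm.merge_sites(coords2d, amps, merge_radius_mm=3.0)
motor_map = tm.interpolate_map(merged_xy, merged_amp, resolution_mm=1.0,
                               muscle=muscle, intensity="110")

metrics = tm.map_metrics(motor_map, threshold_uv=50.0)
true_r = truth.fields["S01"][muscle].suprathreshold_radius(50.0, 110.0)
print(f"{muscle} map at 110% rMT, 50 uV threshold:")
print(f"  area    : {metrics.area_mm2:7.0f} mm^2 "
      f"(analytic field: {np.pi * true_r**2:.0f} mm^2)")
print(f"  volume  : {metrics.volume_mm2_uv:9.0f} mm^2.uV")
print(f"  centroid: ({metrics.centroid_mm[0]:.1f}, {metrics.centroid_mm[1]:.1f}) mm")
levels = tm.contour_fractions(motor_map)
print(f"  contour levels at 5/30/70% of max: "
      f"{levels[0]:.0f}, {levels[1]:.0f}, {levels[2]:.0f} uV")
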