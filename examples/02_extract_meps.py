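"""Extract motor evoked potentials from EMG traces and estimate the rMT.

Builds single trials with known amplitude, applies the peak-to-peak
extraction (10-60 ms window), the pre-activation rejection rule
(±20 µV in the 300 ms before the pulse) and the 5-of-10 > 100 µV resting
motor threshold criterion.
"""

import tmsmap as tm

field = tm.ExcitabilityField(center=(0.0, 0.0), sigma=7.0, peak_amp=500.0)

# a clean trial at the field centre: extraction recovers the amplitude
trial = tm.simulate_trial((0.0, 0.0), {"FCR": field}, 110.0, noise_sd=0.0)
rec = tm.extract_mep(trial.traces["FCR"], trial.trigger_index, trial.sample_rate)
print(f"clean trial    : amplitude {rec.amplitude_uv:.1f} uV "
      f"(field value 500.0), latency {rec.latency_ms:.1f} ms")

# a contaminated trial: baseline activity forces rejection
bad = tm.simulate_trial((0.0, 0.0), {"FCR": field}, 110.0, noise_sd=0.0, artifact=True)
ok = tm.check_preactivation(bad.traces["FCR"], bad.trigger_index, bad.sample_rate)
print(f"artifact trial : accepted={ok} (pre-activation exceeded +-20 uV)")

# median aggregation across the three pulses delivered at one site
print(f"site aggregate : median of [100, 200, 900] uV = "
      f"{tm.aggregate_site([100.0, 200.0, 900.0]):.0f} uV")

# rMT: lowest stimulator intensity with >=5 of 10 MEPs above 100 uV
series = {
    42.0: [80.0] * 10,
    44.0: [150.0] * 4 + [60.0] * 6,
    45.0: [150.0] * 6 + [60.0] * 4,
    47.0: [200.0] * 10,
}
rmt = tm.estimate_rmt(series)
print(f"resting motor threshold: {rmt.rmt_pct_mso:.0f} % MSO "
      f"(found={rmt.found}, at tested boundary={rmt.at_boundary})")
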