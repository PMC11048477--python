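"""Demonstrate artifact sharing between the far detector and the SRS trace.

Motion spikes are injected into the 4 cm channels only (shared spike times,
per-wavelength amplitude jitter). Because SRS combines both separations and
SSDS-4cm reads the far detector, both show the spikes; SSDS-3cm — which
never touches the far detector — stays clean. This locality is one argument
for single-separation oximetry at short distances.
"""

import numpy as np

from nirsox import (
    NoiseModel,
    calibrate_k,
    simulate_recording,
    srs_timeseries,
    ssds_timeseries,
)

noise = NoiseModel(
    cardiac_amp_um=0, resp_amp_um=0, mayer_amp_um=0,
    drift_rel_per_min_sd=0, hold_fluct_sd_pct=0,
    white_sd_rel=0.001, spike_rate_hz=0.05, spike_amp_rel=0.2, seed=4,
)
sim = simulate_recording(noise=noise, mode="diffusion")
spike_times = np.asarray(sim.params["spike_times_s"])
cal = calibrate_k(sim.recording, "source_spec")

traces = {
    "StO2-SRS": srs_timeseries(sim.recording),
    "StO2-SSDS-4cm": ssds_timeseries(sim.recording, cal, 4.0),
    "StO2-SSDS-3cm": ssds_timeseries(sim.recording, cal, 3.0),
}

print(f"injected spikes at t = {np.round(spike_times, 1)} s (4 cm channels only)")
print(f"{'trace':>15} {'max excursion at spikes':>24}")
for name, trace in traces.items():
    idx = np.clip(np.searchsorted(trace.time, spike_times) + 2, 0, trace.sto2.size - 1)
    clean = np.ones(trace.sto2.size, dtype=bool)
    for i in idx:
        clean[max(0, i - 5): i + 120] = False
    center = float(np.nanmedian(trace.sto2[clean]))
    exc = float(np.nanmax(np.abs(trace.sto2[idx] - center)))
    print(f"{name:>15} {exc:20.2f} %")
print()
print("Spikes surface in SRS and SSDS-4cm but not SSDS-3cm: artifacts travel")
print("with the detector channel, not with the estimation method.")
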