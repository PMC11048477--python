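"""Simulate a noiseless breath-hold recording and recover StO₂ with the
single source–detector separation (SSDS) estimator.

Under the Beer–Lambert-exact forward mode the estimator is algebraically
exact, so the recovered saturation trace should match the ground truth to
numerical precision — this is the package's central correctness property.
"""

import numpy as np

from nirsox import NoiseModel, calibrate_k, simulate_recording, ssds_timeseries

sim = simulate_recording(noise=NoiseModel.silent(0), mode="mbll-exact")
cal = calibrate_k(sim.recording, "source_spec")
trace = ssds_timeseries(sim.recording, cal, separation_cm=3.0)

err = np.max(np.abs(trace.sto2 - sim.truth["sto2"].to_numpy()))
print(f"baseline StO2 (truth):        {sim.truth['sto2'].iloc[0]:.2f} %")
print(f"peak StO2 (truth):            {sim.truth['sto2'].max():.2f} %")
print(f"SSDS-3cm estimate at peak:    {np.nanmax(trace.sto2):.2f} %")
print(f"max |estimate - truth|:       {err:.2e} percentage points")
print()
print("The estimate tracks the simulated breath-hold response (dip at ~10 s,")
print("supra-baseline peak at ~27.5 s after onset) exactly: on the homogeneous")
print("tissue model the formula's pathlength and coupling terms cancel.")
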