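"""Simulate a virtual type 2 diabetes patient.

Builds a 7-day "typical regime" patient (pre-meal and 2h-post-meal glucose
readings around three meals a day), prints the monitoring summary and a few
measurements.  Every downstream example starts from a patient like this one.
"""

from glucoda.synth import CohortConfig, simulate_patient

config = CohortConfig(model_id="ultradian", regime="typical", n_days=7,
                      measurement_noise_sd=10.0, seed=1)
patient = simulate_patient(config)

tl = patient.timeline
print(f"regime={config.regime}, days={config.n_days}")
print(f"meals recorded:        {len(tl.meals)}")
print(f"glucose measurements:  {tl.n_measurements}")
print(f"ground-truth glucose:  mean {patient.truth.glucose.mean():.1f} mg/dl, "
      f"range [{patient.truth.glucose.min():.0f}, {patient.truth.glucose.max():.0f}]")
print("\nfirst measurements (time min, mg/dl, tag):")
print(tl.measurements.head(6).to_string(index=False))

# The measurements are the ground truth sampled at the self-monitoring times
# plus meter noise (sd 10 mg/dl): what a real patient's logbook looks like,
# except that here the underlying physiology is known exactly.
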