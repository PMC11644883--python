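"""Generate one synthetic elbow flexion/extension trial and inspect it.

The generator builds 20 s of wrist angular velocity (100 Hz, deg/s) from
alternating half-sine lobes whose amplitude declines linearly across the
trial (fatigue) with cycle-to-cycle jitter, plus drift and sensor noise.
The returned truth object records the noise-free per-cycle values that the
analysis should recover.
"""

from uef import synth

params = synth.MotorSimParams(
    peak_velocity=350.0,   # nominal lobe amplitude, deg/s
    cycle_frequency=1.1,   # flexion+extension cycles per second
    decline_pct=-15.0,     # last-5s mean range is 15% below the first-5s
    cycle_cv=6.0,          # cycle-to-cycle amplitude jitter, %
    noise_sd=8.0,          # white sensor noise, deg/s
    drift_amp=10.0,        # slow 0.1 Hz drift, deg/s
    seed=42,
)
trial, truth = synth.gen_flexion_trial(params)

print(f"samples: {trial.n} at {trial.fs:.0f} Hz ({trial.duration_s:.0f} s)")
print(f"cycles generated: {truth.values['n_cycles']:.0f}")
print(f"true mean velocity range (speed): {truth.values['speed']:.1f} deg/s")
print(f"true mean flexion excursion:      {truth.values['flexibility']:.1f} deg")
print(f"true range CV: {truth.values['cv']:.1f} %   "
      f"true last-vs-first: {truth.values['decline']:.1f} %")
# Speed is twice the mean lobe amplitude; the excursion is the half-sine
# integral A/(pi*f). The decline and CV describe the amplitude schedule.
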