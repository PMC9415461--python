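"""Reduce population time series to dominant Fourier features.

Aggregates a simulated condition to per-parameter population means,
z-scores each 400-point series, and keeps only the DFT bin of maximal
amplitude.  The frequency index k* says how many oscillations the trend
completes over the run (k* = 1 is a monotone drift), the amplitude how
wave-like the series is, and the phase which part of the wave the 20 h
window caught — together one (amplitude, phase) pair per parameter
replaces 400 time points.
"""

from phenofft import AcquisitionConfig, aggregate, builtin_archetypes, \
    center_scale, simulate_trajectories, spectral_features

config = AcquisitionConfig(seed=11)
records = simulate_trajectories(config, builtin_archetypes()["stabilizer"])
series = aggregate(records)["stabilizer"]
features = spectral_features(center_scale(series))

print("stabilizer condition, dominant Fourier feature per parameter:")
print(f"{'parameter':18s} {'k*':>3s} {'period':>7s} {'amplitude':>9s} {'phase':>7s}")
for f in features:
    print(f"{f.parameter:18s} {f.k_star:3d} {f.period:7.1f} "
          f"{f.amplitude:9.3f} {f.phase:7.3f}")
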