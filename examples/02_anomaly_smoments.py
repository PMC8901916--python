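"""Anomaly screening in the suddency-moment domain.

A raw trace is positivized, each sample is mapped to its suddency moment
(the s at which the Lehmer transform reproduces that sample value), and
samples with extreme |s| are flagged.  Large positive s marks unusually
large samples, large negative s unusually small ones — a nonlinear,
noise-robust ranking of how extreme each sample is.
"""

import numpy as np

from suddency import pointwise_inverse_series, preprocess_to_positive, windowed_transform

rng = np.random.default_rng(0)
t = np.arange(1024)
trace = 0.02 * np.sin(2 * np.pi * t / 128) + 0.002 * rng.standard_normal(t.size)  # mV
trace[500] += 0.08  # a transient spike

pos, _ = preprocess_to_positive(trace)  # Lehmer domain requires positivity

# windowed transform at a high suddency moment highlights the spike window
w = windowed_transform(pos, window=256, hop=128, s=5.0)
print("windowed L(5):", np.array2string(w, precision=4))
print(f"largest window: #{np.argmax(w)} (the spike lives in samples 384-640)")

# pointwise suddency moments; upward transients live at large positive s
# (a dense signal's many near-minimum samples legitimately crowd s = -clip,
# so one-sided thresholds are the sharper screen for spikes)
s = pointwise_inverse_series(pos, clip=20.0)
upward = s > 15.0
print(f"\nsamples with s > 15: {upward.sum()} of {len(s)} "
      f"(index {int(np.flatnonzero(upward)[0])}; spike sample s = {s[500]:.2f}, clip at +-20)")
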