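"""The Lehmer transform as a statistic-generating function.

Sweeping the suddency moment s generates the classical statistics of a
sample: s = 0 the harmonic mean, s = 1 the arithmetic mean, s = 2 the
contra-harmonic mean, and the extremes at s = +-infinity.  The inverse
transform maps any statistic value back to its suddency moment.
"""

import numpy as np

from suddency import inverse_lehmer, lehmer_transform

x = np.array([1.0, 2.0, 3.0, 5.0])
print(f"signal: {x}")
for s, name in [(-np.inf, "minimum"), (0, "harmonic mean"), (1, "arithmetic mean"),
                (2, "contra-harmonic mean"), (np.inf, "maximum")]:
    print(f"  L({s:>4}) = {lehmer_transform(x, s):.6f}   ({name})")

# every statistic between min and max has a unique suddency moment
t = 2.0
s = inverse_lehmer(x, t)
print(f"\nthe statistic t = {t} is generated at suddency moment s = {s:.6f}")
print(f"round trip: L({s:.4f}) = {lehmer_transform(x, s):.6f}")
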