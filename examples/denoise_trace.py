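"""Denoise a chromatogram channel with the multilevel Haar transform.

Builds a noisy synthetic trace, strips the high-frequency detail at three
levels, and shows that the additive decomposition f = A3 + D1 + D2 + D3 is
exact while the retained approximation still pins the peak apex.
"""

import numpy as np

from sangerhet import haar_decompose, denoise_channel
from sangerhet.simulate import TraceSimSpec, simulate_trace

trace, _ = simulate_trace(TraceSimSpec(n_bases=40, seed=1))
signal = trace.channels["A"]

dec = haar_decompose(signal, levels=3)
recon = dec.approximations[-1] + sum(dec.details)
err = np.max(np.abs(recon - signal)) / np.max(signal)
print(f"reconstruction error (relative): {err:.2e}")
# ~1e-16: the three detail sub-signals plus A3 reproduce the input exactly.

smooth = denoise_channel(signal, levels=3)
print(f"signal length preserved: {len(smooth) == len(signal)}")

# look at one called base whose peak lives on the A channel
idx = trace.called_bases.index("A", 10)
scan = trace.peak_scans[idx]
lo, hi = scan - 6, scan + 7
raw_apex = lo + int(np.argmax(signal[lo:hi]))
dn_apex = lo + int(np.argmax(smooth[lo:hi]))
print(f"apex scan at base {idx}, raw vs denoised: {raw_apex} vs {dn_apex}")
# The denoised apex stays within one 8-scan block of the raw apex; the
# uniform baseline noise is gone because the detail sub-signals carried it.
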