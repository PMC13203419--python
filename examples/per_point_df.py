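"""Dominant frequency and Organization Index of one electrogram window.

Builds a clean 6.7 Hz activation train, runs the Botteron + Welch chain
on its 2-s window, and prints the DF estimate and the OI significance.
"""

import numpy as np

from hdfmap import botteron_filter, organization_index, pick_df, welch_psd
from hdfmap.synthetic import render_pulse_train

FS = 1000.0
TRUE_DF = 6.7

activations = np.arange(0.03, 2.0, 1.0 / TRUE_DF)
window = render_pulse_train(activations, 2000, FS)

envelope = botteron_filter(window, FS)
spectrum = welch_psd(envelope, FS)
df = pick_df(spectrum)
oi = organization_index(spectrum, df)

print(f"true activation rate : {TRUE_DF:.2f} Hz")
print(f"estimated DF         : {df:.2f} Hz  (4-10 Hz spectral peak)")
print(f"Organization Index   : {oi:.3f}    (significant if >= 0.2)")
# The DF lands on the 0.05 Hz spectral grid next to the true rate; a
# clean periodic train concentrates most 0-20 Hz power in the DF and
# harmonic bands, hence the high OI.
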