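"""Unmix designed five-tag mixtures and check the recovered fractions.

Builds the five simulated nanotag reference spectra, mixes them at eight
designed ratios with 1.5% additive noise, deconvolves each mixture by
non-negative classical least squares, and correlates recovered against
designed fractions.
"""

import numpy as np

from serscyto import (
    DEFAULT_PANEL_DESIGNS,
    REPORTER_ORDER,
    cls_unmix,
    default_reference_library,
    make_mixture_panel,
    recovery_correlation,
)

library = default_reference_library()
panel = make_mixture_panel(library, DEFAULT_PANEL_DESIGNS, noise_sd=0.015, seed=0)

results = []
for fractions, spectrum in panel:
    recovered = cls_unmix(spectrum, library, mode="nnls").as_array()
    results.append((fractions, recovered))

# the QXL680-dominant 1:6:1:1:1 design (second in the default panel)
true, rec = results[1]
rec = rec / rec.sum()
print("design 1:6:1:1:1  (reporter: designed -> recovered fraction)")
for name, t, r in zip(REPORTER_ORDER, true, rec):
    print(f"  {name:7s} {t:.2f} -> {r:.3f}")

corr = recovery_correlation(results)
print(f"\npooled recovery over {corr.n} (design, tag) pairs: r = {corr.r:.4f}, p = {corr.p:.2e}")
print("r near 1 means CLS returns the designed tag proportions despite the noise.")
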