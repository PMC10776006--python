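"""Simulate-then-fit: recover planted DN parameters from noiseless data.

Generates six vertices spanning an early-to-late parameter gradient, runs
the two-stage Gaussian -> DN fit, and prints planted versus recovered
canonical ratios.  At zero noise the ratios are recovered essentially
exactly (the absolute constants are only defined up to a common scale).
"""

import pandas as pd

from dnprf import fit_dn, fit_gaussian, make_bar_sequence, make_grid
from dnprf.synth import TruthSpec, make_truth, simulate_participants

design = make_bar_sequence(make_grid(8.0, 50))
spec = TruthSpec(n_rois=3, vertices_per_roi=2, jitter_sd=0.05, seed=1)
truth = make_truth(spec)

part = simulate_participants(truth, design, 1, snr=None, seed=0, hrf_weight=0.25)[0]

gauss = fit_gaussian(part.run1, design)
fit = fit_dn(part.run1, design, gaussian_fit=gauss)

report = pd.DataFrame({
    "roi": truth.roi,
    "x0_true": part.params.x0.round(2), "x0_fit": fit.x0.round(2),
    "bd_true": (part.params.b / part.params.d).round(3),
    "bd_fit": (fit.b / fit.d).round(3),
    "ad_true": (part.params.a / part.params.d).round(4),
    "ad_fit": (fit.a / fit.d).round(4),
    "r2": fit.r2.round(4),
})
print(report.to_string(index=False))
print("\nb/d falls from ROI 1 to ROI 3 (less suppression up the hierarchy);"
      "\nR2 = 1 and matching ratios show exact noiseless recovery.")
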