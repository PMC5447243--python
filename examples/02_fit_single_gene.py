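"""Fit the field model to a single simulated temperature-responsive gene.

Simulates one gene whose expression integrates heat above 30 C over a 6-h
memory window, runs the full two-step optimization plus adaptive group-lasso
selection, and prints what was recovered.
"""

import warnings

import numpy as np

import fieldfit as ff
from fieldfit.benchmark import benchmark_conditions

schedule, weather = benchmark_conditions("4h")

truth = next(t for t in ff.truth_library(seed=0) if t.structure == {"response"})
rng = np.random.default_rng(1)
mu = 2.0 ** ff.true_log2_mean(truth, schedule, weather)
y = np.log2(rng.negative_binomial(1 / truth.dispersion,
                                  1 / (1 + truth.dispersion * mu)) + 0.5)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = ff.fit_gene(y, None, schedule, weather, gene_id=truth.gene_id)

rp = model.response_params
print(f"truth: factor=temperature, threshold={truth.response_params.threshold_theta} C, "
      f"memory={truth.response_params.period_p} h, groups={sorted(truth.structure)}")
print(f"fitted: factor={model.factor}, groups={sorted(model.nonzero_groups())}")
if rp is not None:
    print(f"        threshold={rp.threshold_theta:.1f} C, memory={rp.period_p:.1f} h, "
          f"gamma_f={rp.gamma_f:.1f} (negative = dose-dependent ramp)")
print(f"        lambda*={model.selected_lambda:.3g}, CV error={model.cv_error:.3f}")
print(
    "\nA matching group set and a threshold/memory near the truth mean the "
    "nonlinear environmental response was identified from 180 noisy samples."
)
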