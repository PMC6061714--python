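"""ASCA: partition retention shifts into per-factor effects, then recover
coefficients from the effect decompositions.

Level means over the balanced factorial core give one effect matrix per
factor; the residual holds interaction, latent and noise structure.  The
conversion-factor bridge applied to the concatenated effect scores yields
coefficients comparable term-for-term with MLR.
"""

import numpy as np

import rtshift as rt

spec = rt.DesignSpec.two_factor_default(center_replicates=5)
design = rt.build_design(spec)
truth = rt.default_ground_truth(spec, seed=3)
ds = rt.simulate_retention(design, truth, seed=3)
X = ds.retention.values

asca = rt.fit_asca(X, design)
print("sum of squares per partition (min^2):")
print(asca.effect_ss.round(2).to_string())

b_asca = rt.asca_coefficients(asca, design)
mlr = rt.fit_mlr(X, design)
for term in ("pH", "temperature", "pH^2", "temperature^2", "pH*temperature"):
    r = np.corrcoef(b_asca.values.loc[term], mlr.values.loc[term])[0, 1]
    print(f"ASCA vs MLR correlation, term {term:15s}: {r: .4f}")
print(
    "\nLarge-effect terms line up on the identity; the near-zero terms "
    "(temperature^2, interaction) scatter because their signal sits below "
    "the run-to-run noise."
)
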