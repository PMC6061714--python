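"""Recover design coefficients from PCA loadings via the conversion factor.

On latent-free noiseless data the scores span the design space exactly, so
the least-squares conversion C_hat (scores -> design columns) turns the
loadings into the same coefficients MLR produces: P' = C_hat B.
"""

import numpy as np

import rtshift as rt

spec = rt.DesignSpec.two_factor_default(center_replicates=5)
design = rt.build_design(spec)
truth = rt.default_ground_truth(spec, noise_sd=0.0, n_latent=0, seed=2)
ds = rt.simulate_retention(design, truth, seed=2)

mlr = rt.fit_mlr(ds.retention.values, design)
pca = rt.fit_pca(ds.retention.values, n_components=5)
conv = rt.fit_conversion(pca.scores, design)
b_pca = rt.coefficients_from_loadings(conv, pca, design)

print("per-term R^2 of the conversion fit D ~ T C:")
print(conv.fit_quality.round(6).to_string())
gap = np.abs(b_pca.values.to_numpy() - mlr.values.to_numpy()).max()
print(f"\nmax |B_pca - B_mlr| over all {b_pca.values.size} coefficients: {gap:.2e}")
print(
    "A gap at machine precision confirms the algebraic identity: the design "
    "information is fully contained in the scores/loadings basis."
)
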