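"""Factor analysis of a synthetic 17-item depression questionnaire.

Generates pre-treatment item scores with a known 6-factor orthogonal
structure, runs the full pipeline (KMO/MSA screening, Kaiser count,
principal-axis extraction, varimax, Anderson-Rubin scoring) and compares
the recovered structure with the planted one.
"""

import numpy as np

import fcresponse as fr

lam = fr.simple_structure_loadings(17, 6, primary=0.8)
spec = fr.SyntheticSpec(n_subjects=500, loading_matrix=lam, seed=7)
q = fr.gen_questionnaire(spec)

model = fr.fit_factor_model(q.pre)
scores, total = fr.score_subjects(model, q.pre)

idx = [q.pre.columns.get_loc(c) for c in model.retained_items]
_, congruence = fr.align_loadings(model.loadings.to_numpy(), lam[idx])
cov_dev = np.abs(
    np.cov(scores.to_numpy().T, ddof=1) - np.eye(model.n_factors)
).max()

print(f"KMO after screening:      {model.kmo:.3f}")
print(f"items dropped:            {model.dropped_items}")
print(f"factors retained (Kaiser): {model.n_factors}")
print(f"variance explained:       {model.variance_explained:.1%}")
print(f"Tucker congruence/factor: {np.round(congruence, 3)}")
print(f"score covariance dev:     {cov_dev:.2e}")
print()
print("KMO > 0.5 means the items are factorable; congruence near 1 says the")
print("varimax solution recovered the planted factors; the covariance")
print("deviation near machine precision is the Anderson-Rubin guarantee of")
print("exactly orthonormal factor scores on the fitting sample.")
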