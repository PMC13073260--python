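"""OPLS-DA screening of a metabolite layer with permutation validation.

Fits a 1+1-component OPLS-DA to model vs control, reports R2Y/Q2 and
VIP, validates by label permutation, and applies the joint
VIP > 1 / p < 0.05 metabolite-calling criterion.
"""

from revnet import (
    SyntheticSpec, fit_oplsda, generate_dataset, screen,
    screen_metabolites, validate_permutation,
)

spec = SyntheticSpec(
    n_features=120, frac_disease=0.3, frac_reversed=0.5,
    effect_log2=2.0, noise_sd=0.5, seed=4, layer="metabolite",
)
matrix, truth = generate_dataset(spec)
two_group = matrix.restrict_groups(("model", "control"))

model = fit_oplsda(two_group, n_orth=1, seed=0)
print(f"R2Y = {model.r2y:.3f}, Q2 = {model.q2:.3f} "
      "(fitted vs 7-fold cross-validated class variance explained)")

perm = validate_permutation(two_group, n_perm=200, seed=0)
print(f"permutation test: mean permuted Q2 = {perm.table['q2'].mean():.3f}, "
      f"empirical p = {perm.p_empirical:.4f} -> separation is not chance")

diff = screen(two_group, ("model", "control"))
selected = screen_metabolites(model, diff, vip_threshold=1.0, p_threshold=0.05)
planted = set(truth.index[truth["disease"]])
print(f"{len(selected)} metabolites pass VIP > 1 and p < 0.05 "
      f"({len(selected & planted)} of {len(planted)} planted ones recovered)")
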