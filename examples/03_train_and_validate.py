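"""Train the calibrated SVM ensemble and validate on held-out peptides.

Trains the sequence-based member zoo on a small planted-motif pool and
reports each member's cross-validation weight and held-out AUROC, plus the
ensemble AUROC — the ensemble should match or beat its typical member.
"""

import numpy as np

import epidesign as ed
from epidesign.core import Label

pool = ed.generate_pool(ed.SyntheticConfig(n_pos=120, n_neg=240, seed=7))
pos, neg = ed.build_pools(pool)
split = ed.make_train_test_split(pos, neg, 60, 120, seed=1)

specs = ed.default_ensemble_specs(
    c_grid=(2.0**-1, 2.0**3, 2.0**7),
    gamma_grid=(2.0**-11, 2.0**-7, 2.0**-3),
    cv_folds=3,
)
model = ed.fit_ensemble(specs, split.train, seed=21)

y = [1 if r.label is Label.POSITIVE else 0 for r in split.test]
peptides = [r.peptide for r in split.test]
P = model.member_probabilities(peptides)

print(f"{'member':24s} {'weight a_j':>10s} {'AUROC':>7s}")
for j, member in enumerate(model.members):
    print(f"{member.spec.name:24s} {member.cv_accuracy:10.3f} {ed.auroc(P[:, j], y):7.3f}")
ens = ed.combine_ensemble(P, model.weights)
print(f"{'ensemble':24s} {'':10s} {ed.auroc(ens, y):7.3f}")
print(f"\nensemble >= median member: {ed.auroc(ens, y) >= np.median([ed.auroc(P[:, j], y) for j in range(P.shape[1])])}")
# Each weight a_j is the member's cross-validation accuracy; the ensemble
# probability is the a_j-weighted average of the member probabilities.
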