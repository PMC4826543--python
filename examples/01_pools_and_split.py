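"""Build binder/non-binder pools from intensities and split train/test.

Generates a synthetic peptide pool at the scale of the original microarray
study (6,841 binders above 10,000 fluorescence units, 20,437 non-binders
below 1,000), then samples the study's training-set sizes.
"""

import epidesign as ed

cfg = ed.SyntheticConfig(n_pos=6841, n_neg=20437, seed=1)
pool = ed.generate_pool(cfg)
positives, negatives = ed.build_pools(pool)
print(f"positive pool (intensity > 10,000): {len(positives)} peptides")
print(f"negative pool (intensity <  1,000): {len(negatives)} peptides")

split = ed.make_train_test_split(positives, negatives, 3420, 10218, seed=2)
print(f"training set: {len(split.train)} peptides (3,420 binders + 10,218 non-binders)")
print(f"test set:     {len(split.test)} peptides (everything left over)")
# The split is disjoint and deterministic for a fixed seed; the sizes match
# the 13,638 / 13,640 partition used to train and validate the classifier.
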