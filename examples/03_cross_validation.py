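"""Cross-validate the default model on a synthetic planted-motif benchmark.

Builds the motif + k-mer + binary feature matrix (with one motif that is
1 + 336 + 123 = 460 columns), makes one stratified 5-fold assignment, and
evaluates extremely randomized trees
with 1,000 estimators — the default classifier — reporting the mean of each
measure over folds.
"""

import sixma as sx

spec = sx.SyntheticSpec(n_pos=200, n_neg=200, motif_strength=1.0, seed=1)
data = sx.generate_dataset(spec)
motifs = [sx.default_planted_motif()]

features = sx.assemble_features(data, sx.EncoderConfig(), motifs)
print(f"feature matrix: {features.n_samples} windows x {features.n_features} features")

folds = sx.make_folds(features.labels, n_folds=5, seed=1)
result = sx.cross_validate(
    features, sx.ClassifierSpec(family="extratrees", n_trees=1000, seed=1), folds
)

print("5-fold cross-validation means (extremely randomized trees):")
for key, value in result.mean.items():
    print(f"  {key:4s} = {value:.3f}")
print("\nWith the motif planted at full strength the classes are nearly"
      "\nseparable, so sensitivity/specificity/AUC sit close to 1;"
      "\nMCC near 1 means almost no errors of either type.")
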