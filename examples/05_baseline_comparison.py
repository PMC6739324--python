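"""Compare the default model against the SVM reference-predictor preset.

Both models see the same stratified 5-fold assignment, so differences in the
measures reflect the feature/classifier choice, not the partition. The
reference preset uses nucleic-shift-density + binary features (164 columns)
with an RBF SVM at C=0.336, gamma=0.02.
"""

import sixma as sx

spec = sx.SyntheticSpec(n_pos=200, n_neg=200, motif_strength=0.6, seed=1)
data = sx.generate_dataset(spec)

# default model: motif + kmer + binary features, extremely randomized trees
features = sx.assemble_features(data, sx.EncoderConfig(), [sx.default_planted_motif()])
folds = sx.make_folds(features.labels, n_folds=5, seed=1)
default_result = sx.cross_validate(
    features, sx.ClassifierSpec(family="extratrees", n_trees=1000, seed=1), folds
)

# reference preset on the same folds
baseline_features, baseline_spec = sx.baseline_idna6ma_pseknc(data)
baseline_result = sx.cross_validate(baseline_features, baseline_spec, folds)

print(f"{'measure':6s} {'trees+motif/kmer/binary':>24s} {'svm nsd+binary':>16s}")
for key in ("sn", "sp", "acc", "mcc", "auc", "f1"):
    print(f"{key:6s} {default_result.mean[key]:>24.3f} {baseline_result.mean[key]:>16.3f}")
print("\nOn this synthetic benchmark the planted signal is positional base"
      "\npreferences, which the density+binary features capture directly, so"
      "\nthe two models land close together (here the SVM baseline is even"
      "\nslightly ahead). Rankings on real windows depend on how much of the"
      "\nsignal lives in k-mer composition and discovered motifs instead.")
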