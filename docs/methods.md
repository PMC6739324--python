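# Methods

## Problem and model

The task is binary classification of fixed-length DNA windows (default
41 nt) centered on a candidate adenine: does the window come from the
neighborhood of an N6-methyladenine (6mA) site or not? The model is a
standard supervised pipeline — deterministic sequence encodings feeding a
discriminative classifier — with no positional alignment, structure, or
genome context beyond the window itself. Its core assumption is that the
local sequence flanking a methylated adenine carries composition and motif
signal that distinguishes it from unmethylated adenine neighborhoods.

## Feature encodings

All encoders are pure functions of the window string; identical input gives
bitwise-identical output across calls and processes.

**k-mer composition.** For each order k, counts of every length-k word over
the L−k+1 sliding windows, normalized by the window count so each block is a
probability distribution (sums to 1 within 1e-12, a tested invariant).
Defaults k ∈ {2,3,4} → 336 features. The normalizing denominator is the
number of windows actually scanned; any other choice would break the
distribution property.

**k-spaced nucleotide pairs (KSNPF).** For gap k, the ordered pair
(position i, position i+k+1) — exactly k bases strictly between — is counted
over the L−k−1 valid start positions and divided by L−k−1. The index
convention and the denominator are two faces of the same definition: there
are exactly L−k−1 such pairs, so each block also sums to 1. Defaults
k ∈ {1,2,3,4} → 64 features.

**Nucleic shift density (NSD).** d_i is the frequency of the base at
position i within the length-i prefix; position 1 is always 1. One feature
per position (41 for the default window). The single-nucleotide trace
(`nsd_trace`) is also exposed because its worked example — the C-trace of
CAGCTG: 1, 0.5, 1/3, 0.5, 0.4, 1/3 — is the clearest statement of the
definition and is used as a reference value in the tests and the acceptance
script.

**Binary code.** Three bits per base on the purine/pyrimidine, weak/strong,
amino/keto axes: A=(1,1,1), C=(0,0,1), G=(1,0,0), T=(0,1,0). The four
triples are pairwise distinct, so the code is invertible (`decode_binary`
exists and round-trips, a tested property). 3L features.

**Motif scores.** One scalar per motif: the maximum over all length-w
windows (optionally also over the reverse complement) of the column-summed
log-odds `log2((p+ε)/(b+ε))` with pseudocount ε = 1e-6 and uniform
background by default. Max pooling is the design choice where several
conventions exist (probability products, scan p-values): it yields one
scalar per motif, is the common PWM-scanning practice, and is checked
against an independent brute-force all-windows loop in the tests. Forward
strand only by default, since methylation is strand-specific; reverse-
complement scanning is a flag.

Motifs are parsed from MEME minimal format. The parser is ours rather than
Biopython's because Biopython's minimal-format reader converts letter
probabilities into integer site counts and renormalizes, perturbing the
probabilities (0.91 → 0.857 at nsites=20) and hence every downstream
log-odds score. Parsing enforces: row count equals the declared width, rows
sum to 1 within 1e-3 (motif files print rounded values), probabilities in
[0,1]. Motifs are kept when E-value < 0.05, the usual significance cut for
enriched motifs.

## Datasets and hygiene

FASTA reading normalizes case and maps U→T; any other letter is either a
hard error (`strict`, default) or drops the record with a logged count
(`drop`). Silent alteration is never performed — an N inside a window would
otherwise corrupt features invisibly.

Exact duplicate sequences within a class are removed (first occurrence
kept). A sequence labeled both positive and negative is contradictory
training signal, so all its copies are removed and the conflict logged.
Similarity-based redundancy reduction (CD-HIT-style clustering) is out of
scope; users wanting identity-threshold filtering should pre-filter with the
external tool.

Stratified 80/20 splitting draws `round(class_size × fraction)` test
records per class with a seeded RNG; membership is deterministic per seed
and the split partitions the input exactly.

## Classifiers and protocol

Five families behind one interface: extremely randomized trees (default),
random forest, gradient boosting, AdaBoost — all at 1,000 estimators by
default — and an RBF SVM (defaults C=0.98, γ=0.01; the preset
`baseline_idna6ma_pseknc` fixes C=0.336, γ=0.02 over density+binary
features, reproducing the reference predictor configuration).

Tree families consume raw features. SVM features are min-max scaled to
[0,1] with the scaler fitted inside the sklearn pipeline, i.e. on training
folds only — scaling on the full matrix would leak held-out information.
All stochastic components take explicit seeds (default 1).

Scores are probability-like values in [0,1] with the decision boundary at
0.5: tree families report the positive-class probability; the SVM's
decision-function value is squashed through a logistic. The squash is
strictly monotone, so rank-based measures (AUC, AP) are identical to using
the raw margin, while hard calls at 0.5 coincide with the SVM's own sign
rule — this reconciles determinism (no internal calibration CV) with a
uniform score scale.

Cross-validation uses a stratified fold assignment built once
(`make_folds`) and passed to every classifier family, so family comparisons
see identical partitions; the assignment is never mutated (tested).
Per-fold reports are averaged arithmetically; the mean is recomputed
independently in tests. Jackknife mode is leave-one-out with one pooled
report over all n held-out predictions. SVM grid search evaluates the full
C × γ grid by mean cross-validated AUC with ties broken toward smaller C,
then smaller γ (deterministic argmax); the default grids are log2-spaced
and include the known-good benchmark optima so a 1×1 grid reproduces them.

## Evaluation measures

Sn, Sp, ACC and MCC are computed from the error-fraction formulation
(misses FN out of N+ positives, false alarms FP out of N− negatives):

    Sn = 1 − FN/N+        Sp = 1 − FP/N−
    ACC = 1 − (FN+FP)/(N+ + N−)
    MCC = (1 − (FN/N+ + FP/N−)) / sqrt((1 + (FP−FN)/N+)(1 + (FN−FP)/N−))

which is algebraically identical to the confusion-matrix MCC; the identity
is exercised numerically to 1e-12 over random count tuples. MCC with a zero
denominator is defined as 0 (logged). F1 is the harmonic mean of precision
and recall with the 6mA class positive; with no predicted and no actual
positives it is 0. Hard calls default to score ≥ 0.5.

ROC/AUC and precision-recall/AP go through scikit-learn (grouped-threshold
curves, trapezoidal AUC, step-sum AP) but are verified against independent
oracles in the tests: AUC against the brute-force Mann–Whitney pairwise
statistic (ties counted 1/2) to 1e-12, AP against a hand-enumerated
threshold sum.

## Synthetic benchmark generator

The generator emulates the balanced benchmark shape: n_pos + n_neg windows
of 41 nt drawn from a background composition (uniform by default; class
sizes of 200+200 are the default desk-scale condition used in the signal-
recovery tests). Positives are overwritten across a planted motif span with
letters sampled column-wise from `strength · p_motif + (1−strength) ·
background` — a continuous difficulty dial: strength 0 makes the classes
statistically exchangeable (chance-level AUC is a tested null), strength 1
plants the motif columns verbatim (AUC ≥ 0.95 recovery is tested). The
default planted matrix is a sharpened consensus ACCGATCSA (0.91 on the
consensus letter, the degenerate S column split 0.45/0.45 between C and G),
echoing the kind of short enriched motif discovery tools report around 6mA
sites; the motif is centered on the window midpoint by default.

`center_a` (default true) forces A at the center position of **both**
classes, not only positives: windows represent candidate adenine sites, so
in real benchmarks negatives are also adenine-centered and the center base
carries no class signal. Forcing it on one class only would make the null
(strength-0) benchmark trivially separable and invalidate the chance-level
control.

What the generator does *not* emulate: genomic composition beyond a single
4-vector, dinucleotide autocorrelation, near-duplicate windows, species
mixtures, or label noise. Passing the recovery and null tests therefore
shows the pipeline is wired correctly and sensitive to planted signal — it
does not certify accuracy figures on real methylomes.

## Numerical and degenerate-input choices

- Encoders reject sequences shorter than the largest k / motif width with
  explicit errors; ambiguous letters never reach an encoder.
- A positive-window center that is not A is a warning-level concern, not an
  error: validation is by construction in the generator and by the user's
  dataset otherwise.
- Probability rows of parsed motifs may be off 1 by up to 1e-3 (files print
  rounded values); beyond that parsing fails rather than renormalizing.
- Fold construction requires each class to have at least as many members as
  folds; folds containing a single class abort cross-validation explicitly.

## Problem sizes

Default test and acceptance runs use 41-nt windows, 200+200 synthetic
samples, 5 folds, and 1,000 trees for the headline signal-recovery check
(smaller ensembles where the check concerns protocol mechanics rather than
accuracy). These sizes were chosen as the smallest at which the recovery
and null contrasts are clearly resolved.

## Known limitations

- Only exact-duplicate removal ships; no similarity clustering.
- Motif *discovery* is out of scope — the package consumes motif files.
- The scoring convention of the original motif-score feature is not
  standardized across tools; ours is max log-odds (documented above), so
  absolute motif-feature values are not comparable across packages, though
  any monotone-equivalent choice trains equivalently for tree models.
- Published benchmark accuracy figures require the original mouse/rice
  window sets, which are not redistributed here; the package reproduces the
  *protocol*, and its quantitative acceptance surface is the worked
  examples, dimension claims, algebraic identities, oracle agreements and
  synthetic recovery/null contrasts above.
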