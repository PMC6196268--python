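"""Validate a reduced 12-miRNA signature by Monte-Carlo cross-validation.

Ridge classifiers are fit on 100 random stratified splits; the accuracy
distribution is compared against a permuted-label null with the two-sample
Kolmogorov-Smirnov test.  A tiny KS p-value says the signature's performance
is not a fluke of the splitting.
"""

from nksig.preprocess import preprocess_chain
from nksig.simulate import generate_microarray
from nksig.validation import validate_signature

matrix, metadata, truth = generate_microarray(seed=0)
normalized = preprocess_chain(matrix, metadata)

signature12 = truth.up[:6] + truth.down[:6]
report = validate_signature(normalized, metadata, signature12,
                            R_true=100, R_perm=100, seed=0)

print(f"12-miRNA signature, Monte-Carlo CV over 100 splits:")
print(f"  mean accuracy (true labels):     {report.mean_accuracy:.1%}")
print(f"  mean accuracy (permuted labels): {report.accuracy_perm.mean():.1%}")
print(f"  KS statistic D = {report.ks_statistic:.2f}, "
      f"p = {report.ks_pvalue:.2e}")
print("\nTrue-label accuracy near 100% with a chance-level permuted null and "
      "a vanishing KS p-value is the signature-reliability pattern the "
      "validation stage is designed to demonstrate.")
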