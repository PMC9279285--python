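"""Scoring a predicted complex catalog against a reference.

The Composite Score sums three complementary metrics: the Maximum Matching
Ratio (how much total overlap a one-to-one matching of references to
predictions can realize), the Overlap (how many references get any decent
match), and the Accuracy (geometric mean of clustering sensitivity and
positive predictive value). A perfect catalog scores 3.0.
"""

from cofrac import evaluate_catalog, overlap_omega, simpson_index

reference = {
    "proteasome_like": {"a1", "a2", "a3", "a4"},
    "exosome_like": {"b1", "b2", "b3"},
    "chaperonin_like": {"c1", "c2", "c3", "c4", "c5"},
}

predicted = {
    "pred1": {"a1", "a2", "a3", "a4"},        # exact recovery
    "pred2": {"b1", "b2", "x9"},              # partial recovery
    "pred3": {"d1", "d2", "d3"},              # spurious
}

report = evaluate_catalog(predicted, reference)
print(report.summary())
print("\nper-reference best matches:")
print(report.matches.to_string(index=False))

print("\npairwise overlap of the partial match:")
print(f"  omega  = {overlap_omega(reference['exosome_like'], predicted['pred2']):.3f}")
print(f"  Simpson = {simpson_index(reference['exosome_like'], predicted['pred2']):.3f}")
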