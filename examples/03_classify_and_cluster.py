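"""From co-elution features to called interactions and predicted complexes.

Trains the random forest on a complex-wise split of the planted complexes
(whole complexes held out, so evaluation pairs never leak into training),
calls pairs at the 0.625 score cutoff, and partitions one condition's
network into complexes by cohesiveness clustering. Precision is the share
of called held-out pairs that are truly co-complex; FDR is its complement.
"""

from cofrac import (
    ReferenceComplexSet,
    attach_features,
    build_training_pairs,
    call_ppis,
    cluster_network,
    precision_fdr,
    train_classifier,
)
from cofrac.benchmark import simulate_benchmark
from cofrac.synth import SimulationConfig

config = SimulationConfig(n_proteins=150, n_complexes=14, n_fractions=96, seed=1)
data = simulate_benchmark(seed=1, config=config)

reference = ReferenceComplexSet(dict(data.truth.complexes), source="planted")
detected = sorted(set(data.features["protein_a"]) | set(data.features["protein_b"]))
split = build_training_pairs(
    reference, detected, seed=1,
    candidate_pool=zip(data.features["protein_a"], data.features["protein_b"]),
)
rows = attach_features(split.train, data.features)
model = train_classifier(rows, rows["label"], seed=1)
network = call_ppis(model, data.features, cutoff=0.625)

heldout = set().union(*(reference.complexes[n] for n in split.test_complexes))
report = precision_fdr(network, reference, restrict_proteins=heldout)
print(f"called {int(network.pairs['called'].sum())} pairs at cutoff 0.625")
print(f"held-out precision = {report.precision:.3f} (FDR = {report.fdr:.3f}) "
      f"over {report.n_evaluated} evaluated pairs")

clusters = cluster_network(network.called("cond1"), condition="cond1")
print(f"\ncond1: {len(clusters)} predicted complexes")
for c in clusters[:5]:
    print(f"  size {len(c.members):2d}  cohesiveness {c.cohesiveness:.2f}  "
          f"density {c.density:.2f}")
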