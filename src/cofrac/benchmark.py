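"""Reproducible default-scale benchmark of the full inference chain.

Runs the simulator at its default study design (500 proteins, 50 planted
complexes, 192 fractions, 3 conditions x 2 replicates, 5% replicate noise,
5% missing identifications), then measures:

* average per-protein replicate Pearson r after filtering/normalization;
* precision of called pairs from held-out planted complexes at the 0.625
  classifier cutoff, against planted co-complex truth;
* conservation-class recovery of planted condition-specific vs shared
  complexes.

Everything derives from one seed; the same numbers are recomputed by the
acceptance script and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import (
    DEFAULT_CUTOFF,
    PPINetwork,
    ReferenceComplexSet,
    attach_features,
    build_training_pairs,
    call_ppis,
    precision_fdr,
    train_classifier,
)
from .coelution import feature_table
from .differential import match_across_conditions
from .pipeline import stage_seed
from .preprocess import filter_single_fraction, normalize, replicate_pearson
from .synth import GroundTruth, SimulationConfig, generate_ground_truth, simulate_elution

__all__ = ["BenchmarkData", "simulate_benchmark", "replicate_agreement",
           "heldout_precision", "conservation_recovery"]


@dataclass
class BenchmarkData:
    """Simulated matrices plus everything derived from them."""

    config: SimulationConfig
    truth: GroundTruth
    design: pd.DataFrame
    matrices: dict
    normalized: dict
    features: pd.DataFrame


def simulate_benchmark(
    seed: int, config: SimulationConfig | None = None, with_features: bool = True
) -> BenchmarkData:
    """Simulate the default benchmark and preprocess it end to end."""
    cfg = config if config is not None else SimulationConfig(seed=seed)
    truth = generate_ground_truth(cfg)
    matrices, design = simulate_elution(truth, cfg)
    normalized = {}
    for ch in design["channel"]:
        kept, _ = filter_single_fraction(matrices[ch])
        normalized[ch] = normalize(kept)
    features = (
        feature_table(normalized, design) if with_features else pd.DataFrame()
    )
    return BenchmarkData(
        config=cfg,
        truth=truth,
        design=design,
        matrices=matrices,
        normalized=normalized,
        features=features,
    )


def replicate_agreement(data: BenchmarkData) -> tuple[float, int]:
    """Average per-protein replicate Pearson r over all condition/replicate
    pairs; returns ``(mean_r, n_proteins_averaged)``."""
    rs = []
    n = 0
    for cond in sorted(data.design["condition"].unique()):
        chans = list(
            data.design.loc[data.design["condition"] == cond, "channel"]
        )
        for i in range(len(chans)):
            for j in range(i + 1, len(chans)):
                agr = replicate_pearson(
                    data.normalized[chans[i]], data.normalized[chans[j]]
                )
                rs.append(agr.per_protein)
                n += len(agr.per_protein)
    pooled = pd.concat(rs)
    return float(pooled.mean()), n


def heldout_precision(
    data: BenchmarkData, cutoff: float = DEFAULT_CUTOFF
) -> tuple[float, int, PPINetwork]:
    """Precision (%) of called held-out pairs against planted truth.

    The classifier is trained on a complex-wise 70/30 split of the planted
    complexes; evaluation keeps called pairs whose proteins both belong to
    held-out complexes and counts a pair correct when it is intra-complex in
    the planted truth. Returns ``(precision_pct, n_evaluated, network)``.
    """
    reference = ReferenceComplexSet(dict(data.truth.complexes), source="planted")
    detected = sorted(
        set(data.features["protein_a"]) | set(data.features["protein_b"])
    )
    split = build_training_pairs(
        reference,
        detected,
        seed=stage_seed(data.config.seed, "split"),
        candidate_pool=zip(data.features["protein_a"], data.features["protein_b"]),
    )
    rows = attach_features(split.train, data.features)
    model = train_classifier(
        rows, rows["label"], seed=stage_seed(data.config.seed, "forest")
    )
    network = call_ppis(model, data.features, cutoff=cutoff)
    heldout = set().union(
        *(reference.complexes[n] for n in split.test_complexes)
    )
    report = precision_fdr(network, reference, restrict_proteins=heldout)
    precision = 0.0 if report.precision is None else 100.0 * report.precision
    return precision, report.n_evaluated, network


def conservation_recovery(data: BenchmarkData) -> tuple[float, int]:
    """Fraction of planted complexes classed as expected across conditions.

    Per-condition catalogs hold each present complex's detected membership;
    condition-specific complexes should class as ``differential``, fully
    shared ones as ``conserved``. Returns ``(fraction_correct, n_records)``.
    """
    catalogs: dict[str, dict[str, set]] = {}
    for cond in sorted(data.design["condition"].unique()):
        chans = list(
            data.design.loc[data.design["condition"] == cond, "channel"]
        )
        detected = set.intersection(
            *(set(data.normalized[ch].data.index) for ch in chans)
        )
        catalogs[cond] = {
            cid: set(members) & detected
            for cid, members in data.truth.complexes.items()
            if data.truth.presence[cid][cond] and (set(members) & detected)
        }
    records = match_across_conditions(catalogs)
    specific = set(data.truth.condition_specific_ids())
    n_ok = 0
    for rec in records:
        expected = "differential" if rec.complex_id in specific else "conserved"
        n_ok += rec.conservation == expected
    return (n_ok / len(records) if records else 0.0), len(records)
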