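"""End-to-end orchestration: config, seeding, staging and the multiplex planner.

The pipeline runs simulate -> filter/normalize -> co-elution features ->
classifier -> interaction calls -> clustering -> evaluation -> differential
comparison, writing TSV artifacts and a manifest (parameters, package
version, sha256 of every output) to an output directory. A single global
seed fans out to per-stage seeds through ``numpy.random.SeedSequence`` so
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
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
from .clusterone import (
    DEFAULT_MIN_DENSITY,
    DEFAULT_MIN_SIZE,
    DEFAULT_OVERLAP,
    DEFAULT_PENALTY,
    catalog_to_frame,
    cluster_network,
)
from .coelution import feature_table
from .differential import differential_report, partition_sets
from .evaluate import DEFAULT_OMEGA_MIN, evaluate_catalog
from .io import write_matrices
from .preprocess import (
    filter_single_fraction,
    joint_column_normalize,
    normalize,
    replicate_pearson,
)
from .synth import SimulationConfig, generate_ground_truth, simulate_elution

__all__ = [
    "PipelineConfig",
    "MultiplexPlan",
    "StageError",
    "plan_multiplex",
    "run_pipeline",
    "stage_seed",
]

log = logging.getLogger("cofrac")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class MultiplexPlan:
    """Injection arithmetic of a multiplexed vs label-free design."""

    injections_labelfree: int
    injections_multiplexed: int
    fold_reduction: float
    max_duplex_biospecimens: int


def plan_multiplex(
    n_conditions: int, n_replicates: int, n_fractions: int, plex: int
) -> MultiplexPlan:
    """Plan LC/MS injections for pooling ``n_conditions x n_replicates``
    fractionations into *plex*-channel barcoded runs.

    Label-free requires one injection per (condition, replicate, fraction);
    pooling needs one injection per fraction per batch of ``plex`` channels.
    Duplicate designs fit ``plex // 2`` distinct biospecimens per run.
    """
    if min(n_conditions, n_replicates, n_fractions, plex) < 1:
        raise ValueError("all planner arguments must be >= 1")
    labelfree = n_conditions * n_replicates * n_fractions
    multiplexed = n_fractions * math.ceil(n_conditions * n_replicates / plex)
    return MultiplexPlan(
        injections_labelfree=labelfree,
        injections_multiplexed=multiplexed,
        fold_reduction=labelfree / multiplexed,
        max_duplex_biospecimens=plex // 2,
    )


_SYNTH_FIELDS = {f.name for f in fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    """Flat, versioned pipeline configuration.

    Round-trips losslessly through YAML; unknown keys are rejected on load.
    Field names mirror the stage parameters they feed; simulator fields are
    prefixed ``synth_``.
    """

    config_version: int = 1
    seed: int = 0
    out_dir: str = "cofrac_out"
    log_level: str = "INFO"
    #: optional directory of existing matrices; empty -> simulate
    input_dir: str = ""
    #: optional reference complex file; empty -> planted truth is the reference
    reference_file: str = ""

    # simulator (see SimulationConfig for semantics)
    synth_n_proteins: int = 500
    synth_n_complexes: int = 50
    synth_min_complex_size: int = 3
    synth_max_complex_size: int = 12
    synth_n_fractions: int = 192
    synth_n_conditions: int = 3
    synth_n_replicates: int = 2
    synth_peak_width_sd: float = 2.0
    synth_co_elution_jitter_sd: float = 0.5
    synth_replicate_noise_cv: float = 0.05
    synth_missing_rate: float = 0.05
    synth_condition_specific_fraction: float = 0.3
    synth_multi_complex_fraction: float = 0.1
    synth_abundance_shift_fraction: float = 0.2
    synth_abundance_shift_fold: float = 3.0

    # feature + classifier stage
    min_overlap_fractions: int = 2
    negative_ratio: float = 5.0
    test_fraction: float = 0.3
    cutoff: float = DEFAULT_CUTOFF

    # clustering stage
    clusterone_penalty: float = DEFAULT_PENALTY
    clusterone_overlap: float = DEFAULT_OVERLAP
    clusterone_min_size: int = DEFAULT_MIN_SIZE
    clusterone_min_density: float = DEFAULT_MIN_DENSITY

    # evaluation + differential stage
    omega_min: float = DEFAULT_OMEGA_MIN
    si_conserved_min: float = 0.8
    si_differential_max: float = 0.45
    enrichment_min_fold: float = 2.0

    def synth_config(self, seed: int | None = None) -> SimulationConfig:
        kwargs = {
            name[len("synth_") :]: getattr(self, name)
            for name in (f.name for f in fields(self))
            if name.startswith("synth_")
        }
        return SimulationConfig(seed=self.seed if seed is None else seed, **kwargs)

    # -- persistence ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {unknown}")
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs: Any) -> Path:
    df.to_csv(path, sep="\t", index=False, **kwargs)
    return path


class _Stage:
    """Context manager: stage timing + failure attribution."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            log.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
            if not isinstance(exc, StageError):
                raise StageError(f"stage {self.name!r} failed: {exc}") from exc
            return False
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return the artifact manifest.

    Deterministic for a fixed seed: rerunning with the same config produces
    byte-identical report TSVs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # fail-fast validation before any compute
    if config.reference_file and not Path(config.reference_file).exists():
        raise FileNotFoundError(
            f"reference complex file not found: {config.reference_file}"
        )
    if config.input_dir and not Path(config.input_dir).exists():
        raise FileNotFoundError(f"input matrix directory not found: {config.input_dir}")

    truth = None
    with _Stage("data"):
        if config.input_dir:
            from .io import read_matrices

            matrices, design = read_matrices(config.input_dir)
        else:
            scfg = config.synth_config(seed=stage_seed(config.seed, "synth"))
            truth = generate_ground_truth(scfg)
            matrices, design = simulate_elution(truth, scfg)
            artifacts["matrices"] = write_matrices(matrices, design, out / "matrices")
            truth_ref = ReferenceComplexSet(
                complexes=dict(truth.complexes), source="planted"
            )
            truth_ref.to_file(out / "planted_complexes.tsv")
            artifacts["planted_complexes"] = out / "planted_complexes.tsv"

    with _Stage("preprocess"):
        filtered, reports, normalized = {}, [], {}
        for ch in design["channel"]:
            kept, report = filter_single_fraction(matrices[ch])
            report.insert(0, "channel", ch)
            reports.append(report)
            filtered[ch] = kept
            normalized[ch] = normalize(kept)
        artifacts["filter_report"] = _write(
            pd.concat(reports, ignore_index=True), out / "filter_report.tsv"
        )
        rep_rows = []
        for cond in sorted(design["condition"].unique()):
            chans = list(design.loc[design["condition"] == cond, "channel"])
            for i in range(len(chans)):
                for j in range(i + 1, len(chans)):
                    agr = replicate_pearson(normalized[chans[i]], normalized[chans[j]])
                    rep_rows.append(
                        {
                            "condition": cond,
                            "channel_a": chans[i],
                            "channel_b": chans[j],
                            "mean_r": agr.mean_r,
                            "mean_r_squared": agr.mean_r_squared,
                            "n_proteins": len(agr.per_protein),
                            "n_excluded": len(agr.excluded),
                        }
                    )
        artifacts["replicate_pearson"] = _write(
            pd.DataFrame(rep_rows), out / "replicate_pearson.tsv"
        )

    with _Stage("features"):
        features = feature_table(
            normalized, design, min_overlap_fractions=config.min_overlap_fractions
        )
        artifacts["features"] = _write(
            features, out / "features.tsv", float_format="%.6g"
        )

    with _Stage("classify"):
        if config.reference_file:
            reference = ReferenceComplexSet.from_file(config.reference_file)
        elif truth is not None:
            reference = ReferenceComplexSet(
                complexes=dict(truth.complexes), source="planted"
            )
        else:
            raise ValueError(
                "no reference complexes: supply reference_file when using "
                "input_dir"
            )
        detected = sorted(
            set(features["protein_a"]) | set(features["protein_b"])
        )
        split = build_training_pairs(
            reference,
            detected,
            negative_ratio=config.negative_ratio,
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, "split"),
            candidate_pool=zip(features["protein_a"], features["protein_b"]),
        )
        train_rows = attach_features(split.train, features)
        model = train_classifier(
            train_rows, train_rows["label"], seed=stage_seed(config.seed, "forest")
        )
        network = call_ppis(model, features, cutoff=config.cutoff)
        artifacts["ppis"] = _write(
            network.pairs, out / "ppis.tsv", float_format="%.6g"
        )
        heldout_universe = set().union(
            *(reference.complexes[n] for n in split.test_complexes)
        )
        report = precision_fdr(network, reference, restrict_proteins=heldout_universe)
        summary = {
            "cutoff": config.cutoff,
            "n_called": report.n_called,
            "n_evaluated_heldout": report.n_evaluated,
            "precision": report.precision,
            "fdr": report.fdr,
        }
        (out / "classifier_report.json").write_text(json.dumps(summary, indent=2))
        artifacts["classifier_report"] = out / "classifier_report.json"

    with _Stage("cluster"):
        catalogs: dict[str, dict[str, set]] = {}
        frames = []
        for cond in sorted(design["condition"].unique()):
            clusters = cluster_network(
                network.called(cond),
                penalty=config.clusterone_penalty,
                overlap_threshold=config.clusterone_overlap,
                min_size=config.clusterone_min_size,
                min_density=config.clusterone_min_density,
                condition=cond,
            )
            frame = catalog_to_frame(clusters, prefix=f"{cond}.CID")
            frames.append(frame)
            catalogs[cond] = {
                row["complex_id"]: set(row["members"].split(";"))
                for _, row in frame.iterrows()
            }
        artifacts["complexes"] = _write(
            pd.concat(frames, ignore_index=True),
            out / "complexes.tsv",
            float_format="%.6g",
        )

    with _Stage("evaluate"):
        eval_rows = []
        for cond in sorted(catalogs):
            rep = evaluate_catalog(
                catalogs[cond], dict(reference.complexes), omega_min=config.omega_min
            )
            eval_rows.append(
                {
                    "condition": cond,
                    "mmr": rep.mmr,
                    "overlap": rep.overlap,
                    "accuracy": rep.accuracy,
                    "composite": rep.composite,
                }
            )
        artifacts["evaluation"] = _write(
            pd.DataFrame(eval_rows), out / "evaluation.tsv", float_format="%.6g"
        )

    with _Stage("differential"):
        ppi_sets = {
            cond: {
                (a, b)
                for a, b in zip(
                    network.called(cond)["protein_a"],
                    network.called(cond)["protein_b"],
                )
            }
            for cond in sorted(design["condition"].unique())
        }
        artifacts["venn_ppis"] = _write(
            partition_sets(ppi_sets), out / "venn_ppis.tsv"
        )
        abundance_matrices = joint_column_normalize(filtered)
        diff = differential_report(
            catalogs,
            matrices=abundance_matrices,
            design=design,
            min_fold=config.enrichment_min_fold,
            conserved_min=config.si_conserved_min,
            differential_max=config.si_differential_max,
        )
        artifacts["differential"] = _write(
            diff, out / "differential.tsv", float_format="%.6g"
        )

    with _Stage("manifest"):
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "outputs": {
                name: {
                    "path": str(p),
                    "sha256": _sha256(p) if p.is_file() else _hash_dir(p),
                }
                for name, p in artifacts.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _hash_dir(path: Path) -> dict[str, str]:
    return {f.name: _sha256(f) for f in sorted(path.iterdir()) if f.is_file()}
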