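"""Synthetic multi-channel co-elution data with planted ground-truth complexes.

The generator emulates the statistical structure of a multiplexed
co-fractionation/MS experiment: native protein complexes eluting as tight
Gaussian peaks over ion-exchange fractions, monomers eluting independently,
conditions multiplexed as isobaric channels (condition x replicate), with
condition-specific complex presence, abundance shifts, replicate-level
multiplicative noise and missing values.

Everything is driven by a single seed; identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

FRACTION_PREFIX = "frac_"

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_elution",
    "fraction_columns",
]


def fraction_columns(n_fractions: int) -> list[str]:
    """Column labels ``frac_0001 .. frac_NNNN`` used by every matrix."""
    return [f"{FRACTION_PREFIX}{i + 1:04d}" for i in range(n_fractions)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic co-elution experiment.

    Defaults describe the study design emulated throughout: 500 detected
    proteins, 50 planted complexes of 3-12 subunits, 192 chromatographic
    fractions, 3 conditions x 2 replicates pooled into a 6-channel multiplex,
    5% replicate noise (coefficient of variation) and 5% missing values.
    """

    n_proteins: int = 500
    n_complexes: int = 50
    min_complex_size: int = 3
    max_complex_size: int = 12
    n_fractions: int = 192
    n_conditions: int = 3
    n_replicates: int = 2
    #: chromatographic peak width (sd, in fractions)
    peak_width_sd: float = 2.0
    #: relative spread of per-assembly peak widths (coefficient of variation);
    #: subunits of one complex share its width, monomers draw their own
    peak_width_cv: float = 0.3
    #: member-to-member apex jitter within a complex (sd, in fractions)
    co_elution_jitter_sd: float = 0.5
    #: multiplicative replicate noise, coefficient of variation
    replicate_noise_cv: float = 0.05
    #: probability that a (protein, fraction) identification is missed
    missing_rate: float = 0.05
    #: fraction of complexes absent from at least one condition
    condition_specific_fraction: float = 0.3
    #: fraction of complex-assigned proteins that join a second complex
    multi_complex_fraction: float = 0.1
    #: fraction of fully shared complexes given an abundance shift
    abundance_shift_fraction: float = 0.2
    abundance_shift_fold: float = 3.0
    #: log-normal sigma of per-protein base amplitudes
    amplitude_sigma: float = 0.5
    amplitude_scale: float = 1e4
    #: intensities below this are not detected (reported as 0)
    detection_limit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if self.n_proteins < 1 or self.n_complexes < 0:
            raise ValueError("n_proteins must be >= 1 and n_complexes >= 0")
        if not (3 <= self.min_complex_size <= self.max_complex_size):
            raise ValueError("complex sizes must satisfy 3 <= min <= max")
        if self.n_conditions < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 condition and >= 1 replicate")
        for name in (
            "peak_width_sd",
            "peak_width_cv",
            "co_elution_jitter_sd",
            "replicate_noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in (
            "condition_specific_fraction",
            "multi_complex_fraction",
            "abundance_shift_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_shift_fold <= 0:
            raise ValueError("abundance_shift_fold must be > 0")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")

    # -- layout helpers -------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return [f"cond{i + 1}" for i in range(self.n_conditions)]

    @property
    def replicates(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replicates)]

    def channel_design(self) -> pd.DataFrame:
        """Channel -> (condition, replicate) map of the multiplex layout."""
        rows = []
        k = 0
        for cond in self.conditions:
            for rep in self.replicates:
                k += 1
                rows.append({"channel": f"ch{k}", "condition": cond, "replicate": rep})
        return pd.DataFrame(rows, columns=["channel", "condition", "replicate"])


@dataclass(frozen=True)
class GroundTruth:
    """Planted complexes and their per-condition presence/abundance."""

    proteins: tuple[str, ...]
    #: complex id -> member protein ids (each complex has >= 3 members)
    complexes: dict[str, frozenset[str]]
    #: complex id -> condition -> present?
    presence: dict[str, dict[str, bool]]
    #: complex id -> condition -> abundance multiplier (> 0)
    multiplier: dict[str, dict[str, float]]
    monomers: tuple[str, ...]

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 3:
                raise ValueError(f"complex {cid} has fewer than 3 members")
        for cid, mult in self.multiplier.items():
            if any(m <= 0 for m in mult.values()):
                raise ValueError(f"complex {cid} has a non-positive multiplier")

    def membership(self, protein: str) -> list[str]:
        return sorted(cid for cid, mem in self.complexes.items() if protein in mem)

    def intra_complex_pairs(self, condition: str | None = None) -> set[frozenset]:
        """All unordered co-complex pairs; optionally only complexes
        present in *condition*."""
        pairs: set[frozenset] = set()
        for cid, members in self.complexes.items():
            if condition is not None and not self.presence[cid][condition]:
                continue
            mem = sorted(members)
            for i, a in enumerate(mem):
                for b in mem[i + 1 :]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def condition_specific_ids(self) -> list[str]:
        return sorted(
            cid for cid, pres in self.presence.items() if not all(pres.values())
        )

    def shared_ids(self) -> list[str]:
        return sorted(cid for cid, pres in self.presence.items() if all(pres.values()))


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    """One global seed fans out to independent per-stage streams."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    return np.random.default_rng(children[stage])


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw planted complexes, their members and per-condition presence.

    Deterministic for a fixed ``config.seed``. A
    ``condition_specific_fraction`` of complexes is present only in a random
    proper subset of conditions; a subset of the fully shared complexes gets
    an ``abundance_shift_fold`` multiplier in one condition.
    """
    rng = _rng_for(config, 0)
    if config.multi_complex_fraction == 0 and (
        config.n_complexes * config.max_complex_size > config.n_proteins
    ):
        raise ValueError(
            "n_complexes * max_complex_size exceeds n_proteins with no "
            "complex overlap allowed"
        )
    width = max(5, len(str(config.n_proteins)))
    proteins = tuple(f"P{i + 1:0{width}d}" for i in range(config.n_proteins))

    sizes = rng.integers(
        config.min_complex_size, config.max_complex_size + 1, config.n_complexes
    )
    if int(sizes.sum()) > config.n_proteins:
        raise ValueError(
            f"planted complexes need {int(sizes.sum())} distinct proteins "
            f"but only {config.n_proteins} are available"
        )
    order = rng.permutation(config.n_proteins)
    cwidth = max(3, len(str(max(config.n_complexes, 1))))
    complexes: dict[str, set[str]] = {}
    cursor = 0
    for k, size in enumerate(sizes):
        cid = f"CPX{k + 1:0{cwidth}d}"
        complexes[cid] = {proteins[i] for i in order[cursor : cursor + int(size)]}
        cursor += int(size)
    assigned = sorted(set().union(*complexes.values())) if complexes else []

    # overlap: promote a fraction of complex proteins into a second complex
    n_multi = int(round(config.multi_complex_fraction * len(assigned)))
    if n_multi and len(complexes) > 1:
        promoted = rng.choice(len(assigned), size=n_multi, replace=False)
        cids = sorted(complexes)
        for idx in sorted(promoted):
            p = assigned[idx]
            hosts = [c for c in cids if p not in complexes[c]]
            if hosts:
                complexes[hosts[int(rng.integers(len(hosts)))]].add(p)

    monomers = tuple(p for p in proteins if p not in set(assigned))

    conditions = config.conditions
    presence: dict[str, dict[str, bool]] = {}
    multiplier: dict[str, dict[str, float]] = {}
    cids = sorted(complexes)
    n_specific = (
        int(round(config.condition_specific_fraction * len(cids)))
        if config.n_conditions > 1
        else 0
    )
    specific_ids = set(
        np.array(cids)[rng.choice(len(cids), size=n_specific, replace=False)]
    ) if n_specific else set()
    for cid in cids:
        if cid in specific_ids:
            n_present = int(rng.integers(1, config.n_conditions))
            chosen = rng.choice(config.n_conditions, size=n_present, replace=False)
            pres = {c: (i in set(chosen.tolist())) for i, c in enumerate(conditions)}
        else:
            pres = {c: True for c in conditions}
        presence[cid] = pres
        multiplier[cid] = {c: 1.0 for c in conditions}

    shared = [cid for cid in cids if all(presence[cid].values())]
    n_shift = int(round(config.abundance_shift_fraction * len(shared)))
    if n_shift and config.n_conditions > 1:
        shifted = rng.choice(len(shared), size=n_shift, replace=False)
        for idx in sorted(shifted):
            cid = shared[idx]
            cond = conditions[int(rng.integers(config.n_conditions))]
            multiplier[cid][cond] = config.abundance_shift_fold

    return GroundTruth(
        proteins=proteins,
        complexes={cid: frozenset(m) for cid, m in complexes.items()},
        presence=presence,
        multiplier=multiplier,
        monomers=monomers,
    )


def _gaussian_profile(center: float, sd: float, n_fractions: int) -> np.ndarray:
    f = np.arange(n_fractions, dtype=float)
    if sd > 0:
        return np.exp(-0.5 * ((f - center) / sd) ** 2)
    out = np.zeros(n_fractions)
    out[int(np.clip(round(center), 0, n_fractions - 1))] = 1.0
    return out


def simulate_elution(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-channel elution matrices for *truth*.

    Per condition, every present complex draws one apex fraction; members
    elute as Gaussian peaks centred at apex + jitter, scaled by the
    protein's base amplitude and the condition multiplier; proteins in
    several present complexes sum their peaks. Monomers elute at independent
    random apexes. Replicate channels of a condition share all apexes and
    differ by multiplicative log-normal noise with the configured
    coefficient of variation. Missing identifications are drawn once per
    (protein, fraction) and shared across every channel of the multiplex,
    mirroring the pooled-injection design in which all channels of a
    fraction come from a single LC/MS run.

    Returns ``(matrices, design)`` where *matrices* maps channel id to a
    protein x fraction DataFrame and *design* is the channel-design table.
    """
    if len(truth.proteins) != config.n_proteins:
        raise ValueError(
            f"truth has {len(truth.proteins)} proteins but config expects "
            f"{config.n_proteins}"
        )
    rng = _rng_for(config, 1)
    n, m = len(truth.proteins), config.n_fractions
    pidx = {p: i for i, p in enumerate(truth.proteins)}

    amplitude = config.amplitude_scale * rng.lognormal(
        0.0, config.amplitude_sigma, size=n
    )

    # per-assembly chromatographic dispersion: every complex (and every
    # monomer) elutes with its own peak width, shared by its subunits
    cids = sorted(truth.complexes)
    if config.peak_width_cv > 0:
        ws = math.sqrt(math.log(1.0 + config.peak_width_cv**2))
        cplx_width = {
            cid: config.peak_width_sd * rng.lognormal(-0.5 * ws**2, ws)
            for cid in cids
        }
        mono_width = {
            p: config.peak_width_sd * rng.lognormal(-0.5 * ws**2, ws)
            for p in sorted(truth.monomers)
        }
    else:
        cplx_width = {cid: config.peak_width_sd for cid in cids}
        mono_width = {p: config.peak_width_sd for p in sorted(truth.monomers)}

    signal = {c: np.zeros((n, m)) for c in config.conditions}
    for cond in config.conditions:
        S = signal[cond]
        for cid in cids:
            if not truth.presence[cid][cond]:
                continue
            apex = rng.uniform(0, m - 1)
            mult = truth.multiplier[cid][cond]
            for p in sorted(truth.complexes[cid]):
                center = apex + rng.normal(0.0, config.co_elution_jitter_sd)
                S[pidx[p]] += (
                    amplitude[pidx[p]]
                    * mult
                    * _gaussian_profile(center, cplx_width[cid], m)
                )
        for p in truth.monomers:
            apex = rng.uniform(0, m - 1)
            S[pidx[p]] += amplitude[pidx[p]] * _gaussian_profile(
                apex, mono_width[p], m
            )

    # shared identification mask: one draw per (protein, fraction)
    detected = rng.random((n, m)) >= config.missing_rate

    cols = fraction_columns(m)
    design = config.channel_design()
    matrices: dict[str, pd.DataFrame] = {}
    sigma = (
        math.sqrt(math.log(1.0 + config.replicate_noise_cv**2))
        if config.replicate_noise_cv > 0
        else 0.0
    )
    for _, row in design.iterrows():
        M = signal[row["condition"]].copy()
        if sigma > 0:
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n, m))
            M *= noise
        M *= detected
        M[M < config.detection_limit] = 0.0
        matrices[row["channel"]] = pd.DataFrame(
            M, index=list(truth.proteins), columns=cols
        )
        matrices[row["channel"]].index.name = "protein_id"
    return matrices, design
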