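"""Cross-condition comparison of interactions and complexes.

Three views of condition differences:

* Venn-style partitions of items (PPIs or complexes) into the 2^k - 1
  nonempty condition-membership regions;
* conservation classes from Simpson's similarity index between best-matched
  complexes across conditions (conserved: min best-SI in [0.8, 1.0];
  differential: < 0.45; intermediate otherwise);
* complex-level abundance from reporter-ion intensities on matrices whose
  fraction totals were normalized jointly across channels (so channel
  ratios survive), with a simple fold-change enrichment call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .evaluate import simpson_index

__all__ = [
    "SI_CONSERVED_MIN",
    "SI_DIFFERENTIAL_MAX",
    "DifferentialRecord",
    "partition_sets",
    "conservation_class",
    "match_across_conditions",
    "complex_abundance",
    "enrichment_call",
    "differential_report",
]

#: best-SI at or above this in every condition pair -> conserved
SI_CONSERVED_MIN = 0.8
#: best-SI strictly below this in some condition pair -> differential
SI_DIFFERENTIAL_MAX = 0.45


def partition_sets(
    items_per_condition: Mapping[str, Iterable],
) -> pd.DataFrame:
    """Venn counts: each distinct item goes to exactly one membership region.

    Returns a table with one row per nonempty condition combination
    (columns: ``conditions`` as ``&``-joined names, ``bitmask``, ``count``).
    Region counts sum to the number of distinct items.
    """
    conditions = sorted(items_per_condition)
    sets = {c: set(items_per_condition[c]) for c in conditions}
    regions: dict[int, int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for item in universe:
        mask = 0
        for i, c in enumerate(conditions):
            if item in sets[c]:
                mask |= 1 << i
        regions[mask] = regions.get(mask, 0) + 1
    rows = []
    for mask in range(1, 2 ** len(conditions)):
        members = [c for i, c in enumerate(conditions) if mask & (1 << i)]
        rows.append(
            {
                "conditions": "&".join(members),
                "bitmask": mask,
                "count": regions.get(mask, 0),
            }
        )
    return pd.DataFrame(rows, columns=["conditions", "bitmask", "count"])


def conservation_class(
    min_best_si: float,
    conserved_min: float = SI_CONSERVED_MIN,
    differential_max: float = SI_DIFFERENTIAL_MAX,
) -> str:
    """Map the minimum cross-condition best-SI onto its conservation band.

    The bands partition [0, 1]: strictly below *differential_max* is
    ``differential``, at or above *conserved_min* is ``conserved``, the rest
    is ``intermediate``.
    """
    if min_best_si < differential_max:
        return "differential"
    if min_best_si >= conserved_min:
        return "conserved"
    return "intermediate"


@dataclass(frozen=True)
class DifferentialRecord:
    """Cross-condition profile of one predicted complex."""

    complex_id: str
    condition: str
    members: frozenset[str]
    #: other condition -> (best partner id, best SI)
    best_si: dict[str, tuple[str | None, float]]
    conservation: str
    abundance: dict[str, float] = field(default_factory=dict)
    enriched_condition: str | None = None
    #: condition -> number of members with no signal there
    missing_members: dict[str, int] = field(default_factory=dict)

    @property
    def min_best_si(self) -> float:
        if not self.best_si:
            return 1.0
        return min(si for _, si in self.best_si.values())


def _best_partner(
    members: frozenset[str], catalog: Mapping[str, Iterable[str]]
) -> tuple[str | None, float]:
    """Best-SI partner; ties broken by larger intersection then lexicographic id."""
    best: tuple[float, int, str] | None = None
    for cid in sorted(catalog):
        other = set(catalog[cid])
        if not other:
            continue
        si = simpson_index(members, other)
        inter = len(members & other)
        # larger SI, then larger intersection, then lexicographically
        # smaller id wins
        if (
            best is None
            or si > best[0]
            or (si == best[0] and inter > best[1])
            or (si == best[0] and inter == best[1] and cid < best[2])
        ):
            best = (si, inter, cid)
    if best is None:
        return None, 0.0
    return best[2], best[0]


def match_across_conditions(
    catalogs: Mapping[str, Mapping[str, Iterable[str]]],
    conserved_min: float = SI_CONSERVED_MIN,
    differential_max: float = SI_DIFFERENTIAL_MAX,
) -> list[DifferentialRecord]:
    """Best-SI matching of every complex against every other condition.

    *catalogs* maps condition -> {complex_id -> member set}. The
    conservation class of a complex derives from the minimum best-SI over
    all other conditions.
    """
    conditions = sorted(catalogs)
    records = []
    for cond in conditions:
        for cid in sorted(catalogs[cond]):
            members = frozenset(catalogs[cond][cid])
            if not members:
                continue
            best: dict[str, tuple[str | None, float]] = {}
            for other in conditions:
                if other == cond:
                    continue
                best[other] = _best_partner(members, catalogs[other])
            min_si = min((si for _, si in best.values()), default=1.0)
            records.append(
                DifferentialRecord(
                    complex_id=cid,
                    condition=cond,
                    members=members,
                    best_si=best,
                    conservation=conservation_class(
                        min_si, conserved_min, differential_max
                    ),
                )
            )
    return records


def complex_abundance(
    members: Iterable[str],
    matrices: Mapping[str, pd.DataFrame],
    design: pd.DataFrame,
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-condition abundance of a complex from member intensities.

    For each condition: the mean over members of the member's total
    intensity across fractions, averaged over that condition's replicate
    channels. *matrices* should be jointly column-normalized (see
    :func:`cofrac.preprocess.joint_column_normalize`); row-normalized
    matrices must not be used, as they erase abundance. A member absent from
    a condition contributes 0 and is counted in the returned missing map.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("complex has no members")
    abundance: dict[str, float] = {}
    missing: dict[str, int] = {}
    for cond in sorted(design["condition"].unique()):
        channels = list(design.loc[design["condition"] == cond, "channel"])
        totals = []
        n_missing = 0
        for p in members:
            per_channel = []
            for ch in channels:
                df = matrices[ch]
                per_channel.append(
                    float(df.loc[p].sum()) if p in df.index else 0.0
                )
            mean_total = sum(per_channel) / len(per_channel)
            if mean_total == 0.0:
                n_missing += 1
            totals.append(mean_total)
        abundance[cond] = sum(totals) / len(totals)
        missing[cond] = n_missing
    return abundance, missing


def enrichment_call(
    abundance: Mapping[str, float], min_fold: float = 2.0
) -> str | None:
    """Condition whose abundance is >= min_fold x every other, else None.

    All-zero vectors and ties return None; a positive single qualifying
    condition is required.
    """
    conds = sorted(abundance)
    winners = [
        c
        for c in conds
        if abundance[c] > 0
        and all(abundance[c] >= min_fold * abundance[d] for d in conds if d != c)
    ]
    return winners[0] if len(winners) == 1 else None


def differential_report(
    catalogs: Mapping[str, Mapping[str, Iterable[str]]],
    matrices: Mapping[str, pd.DataFrame] | None = None,
    design: pd.DataFrame | None = None,
    min_fold: float = 2.0,
    conserved_min: float = SI_CONSERVED_MIN,
    differential_max: float = SI_DIFFERENTIAL_MAX,
) -> pd.DataFrame:
    """Tabular cross-condition report, optionally with abundance columns."""
    records = match_across_conditions(catalogs, conserved_min, differential_max)
    rows = []
    for rec in records:
        row: dict = {
            "complex_id": rec.complex_id,
            "condition": rec.condition,
            "n_members": len(rec.members),
            "min_best_si": rec.min_best_si,
            "conservation": rec.conservation,
        }
        for other, (partner, si) in sorted(rec.best_si.items()):
            row[f"si_vs_{other}"] = si
            row[f"partner_in_{other}"] = partner or ""
        if matrices is not None and design is not None:
            abundance, missing = complex_abundance(rec.members, matrices, design)
            for cond, value in sorted(abundance.items()):
                row[f"abundance_{cond}"] = value
            row["enriched_condition"] = enrichment_call(abundance, min_fold) or ""
            row["n_missing_members"] = sum(missing.values())
        rows.append(row)
    return pd.DataFrame(rows)
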