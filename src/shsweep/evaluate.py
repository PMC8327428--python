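"""Compare threshold partitions with a reference species partition.

A species is *resolved* at a threshold when its reference members form
exactly one cluster and that cluster contains no other reference species —
the formalisation of "strictly distinguished" used throughout.  Unlabelled
query sequences are excluded from status computation (they are reported
with their cluster in the SH table instead).

Thresholds are reported both as distance % (UNITE "0.5%") and similarity %
("99.5%") to prevent unit confusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clustering import Partition, SweepResult
from .io import SpeciesMap

RESOLVED = "resolved"
SPLIT = "split"
MERGED = "merged"
MIXED = "mixed"


@dataclass(frozen=True)
class SpeciesStatus:
    species: str
    status: str
    clusters: tuple[str, ...]


def evaluate_partition(
    partition: Partition, species_map: SpeciesMap
) -> dict[str, SpeciesStatus]:
    """Status per reference species under one partition.

    resolved — one cluster whose reference members equal the species' set;
    split    — >= 2 clusters, each containing only this species;
    merged   — its single cluster also contains other species;
    mixed    — both pathologies at once.
    """
    ref_ids = [i for i in species_map.reference_ids if i in partition.assignment]
    missing = set(species_map.reference_ids) - set(ref_ids)
    if missing:
        raise ValueError(f"reference ids absent from partition: {sorted(missing)}")
    species_of = {i: species_map.species_of(i) for i in ref_ids}
    cluster_refs: dict[str, set[str]] = {}
    for rec_id in ref_ids:
        cluster_refs.setdefault(partition.assignment[rec_id], set()).add(rec_id)

    out: dict[str, SpeciesStatus] = {}
    for sp in species_map.species_labels:
        members = set(species_map.members(sp))
        labels = sorted({partition.assignment[i] for i in members})
        pure = [all(species_of[x] == sp for x in cluster_refs[c]) for c in labels]
        if len(labels) == 1:
            status = RESOLVED if pure[0] else MERGED
        else:
            status = SPLIT if all(pure) else MIXED
        out[sp] = SpeciesStatus(sp, status, tuple(labels))
    return out


def min_resolving_threshold(
    sweep: SweepResult,
    species_map: SpeciesMap,
    scope: Sequence[str] | None = None,
) -> float | None:
    """Smallest grid threshold resolving every species in scope, else None."""
    scope = list(scope) if scope is not None else species_map.species_labels
    if not scope:
        raise ValueError("empty species scope")
    for partition in sweep.partitions:
        statuses = evaluate_partition(partition, species_map)
        if all(statuses[sp].status == RESOLVED for sp in scope):
            return partition.threshold
    return None


def sh_table(sweep: SweepResult, species_map: SpeciesMap | None = None) -> pd.DataFrame:
    """Per-id cluster membership across the grid (Fig-2-style colour bars).

    One row per sequence, one ``cluster@t`` column per grid threshold,
    plus the species label when a map is given.
    """
    ids = sorted(sweep.partitions[0].assignment)
    data: dict[str, list[str]] = {}
    if species_map is not None:
        data["species"] = [
            species_map.species_of(i) if i in species_map else "unknown" for i in ids
        ]
    for partition in sweep.partitions:
        data[f"cluster@{partition.threshold:g}"] = [partition.assignment[i] for i in ids]
    return pd.DataFrame(data, index=pd.Index(ids, name="id"))


@dataclass
class EvalReport:
    """Per-threshold species statuses plus minimal resolving thresholds."""

    grid: tuple[float, ...]
    scope: tuple[str, ...]
    status_table: pd.DataFrame          # species x thresholds, status strings
    cluster_counts: list[int]
    per_species_min: dict[str, float | None]
    overall_min: float | None = field(default=None)

    def to_tsv(self, path: str | Path) -> None:
        df = self.status_table.copy()
        df.index.name = "species"
        df["min_resolving_distance_pct"] = [
            self.per_species_min[sp] for sp in df.index
        ]
        df.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_distance_pct": list(self.grid),
            "grid_similarity_pct": [round(100.0 - t, 6) for t in self.grid],
            "scope": list(self.scope),
            "cluster_counts": self.cluster_counts,
            "statuses": {
                sp: dict(self.status_table.loc[sp]) for sp in self.status_table.index
            },
            "per_species_min_distance_pct": self.per_species_min,
            "overall_min_distance_pct": self.overall_min,
            "overall_min_similarity_pct": (
                None if self.overall_min is None else 100.0 - self.overall_min
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def evaluate_sweep(
    sweep: SweepResult,
    species_map: SpeciesMap,
    scope: Sequence[str] | None = None,
) -> EvalReport:
    """Statuses at every grid threshold and the minimal resolving thresholds.

    The overall minimum is the smallest grid point at which *every* species
    in scope is resolved simultaneously (resolution need not be monotone in
    t, so this is computed directly rather than from per-species minima).
    """
    scope_t = tuple(scope) if scope is not None else tuple(species_map.species_labels)
    if not scope_t:
        raise ValueError("empty species scope")
    per_threshold = {
        p.threshold: evaluate_partition(p, species_map) for p in sweep.partitions
    }
    table = pd.DataFrame(
        {
            f"{t:g}": {sp: st[sp].status for sp in species_map.species_labels}
            for t, st in per_threshold.items()
        }
    )
    per_species_min: dict[str, float | None] = {}
    for sp in species_map.species_labels:
        per_species_min[sp] = next(
            (t for t in sweep.grid if per_threshold[t][sp].status == RESOLVED), None
        )
    overall = next(
        (
            t
            for t in sweep.grid
            if all(per_threshold[t][sp].status == RESOLVED for sp in scope_t)
        ),
        None,
    )
    return EvalReport(
        grid=tuple(sweep.grid),
        scope=scope_t,
        status_table=table,
        cluster_counts=sweep.cluster_counts(),
        per_species_min=per_species_min,
        overall_min=overall,
    )
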