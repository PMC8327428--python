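"""Species-diagnostic alignment columns, query placement, quality screening.

Short or low-quality ITS records carry too little signal for distance
clustering, but they can still be placed against a reference alignment by
the single nucleotide positions that distinguish the species of a complex.
A column is diagnostic for species S with state x when x is present,
unambiguously, in every reference member of S (up to a configurable
tolerated fraction of gap/ambiguous members) and x is never observed in any
other reference species at that column.

Placement compares a query to the diagnostic table: per species we count
covered positions (query has an unambiguous base), matches, mismatches and
uncertain positions (query has an IUPAC ambiguity there).  The verdict is
``assigned`` when exactly one species is mismatch-free and well covered,
``uncertain`` when coverage is short or several species tie, and
``conflicting`` when every species is contradicted — the signature of a
record that matches no species in the reference tree.

Queries are never added to the reference when diagnostics are computed.
Internally columns are 0-based; reports print them 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align

from .distances import encode
from .io import (
    GAP_CHARS,
    IUPAC_AMBIGUITIES,
    IUPAC_BASES,
    Alignment,
    SequenceRecord,
    SpeciesMap,
)

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
UNCERTAIN = "uncertain"
CONFLICTING = "conflicting"

FLAG_FULL_LENGTH = "full_length"
FLAG_PARTIAL_ITS1 = "partial:ITS1"
FLAG_PARTIAL_ITS2 = "partial:ITS2"
FLAG_HIGH_AMBIGUITY = "high_ambiguity"
FLAG_DOMAIN_DEVIANT = "domain_deviant"


@dataclass(frozen=True)
class DiagnosticPosition:
    """One diagnostic entry: ``state`` is fixed in ``species`` at ``column``
    and absent from every other reference species there."""

    column: int
    species: str
    state: str
    observed: Mapping[str, frozenset[str]]  # per-species unambiguous states


@dataclass
class DiagnosticTable:
    positions: list[DiagnosticPosition]
    species: tuple[str, ...]
    n_columns: int

    def __len__(self) -> int:
        return len(self.positions)

    def for_species(self, species: str) -> list[DiagnosticPosition]:
        return [p for p in self.positions if p.species == species]

    def to_dataframe(self) -> pd.DataFrame:
        """Report table with 1-based column indices."""
        rows = []
        for p in self.positions:
            row = {"column_1based": p.column + 1, "species": p.species, "state": p.state}
            for sp in self.species:
                row[f"states:{sp}"] = "".join(sorted(p.observed.get(sp, ())))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def find_diagnostic_positions(
    alignment: Alignment,
    species_map: SpeciesMap,
    tolerance: float = 0.0,
) -> DiagnosticTable:
    """Scan the reference alignment for fixed-and-unique columns.

    ``tolerance`` allows up to that fraction of a species' members to be
    gap/ambiguous at the column (default 0: strictly fixed).  Entries are
    ordered by column index, then species.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must lie in [0, 1]")
    species = species_map.species_labels
    if len(species) < 2:
        raise ValueError("need at least 2 reference species")
    codes = np.vstack([encode(alignment.get(i).seq) for i in alignment.ids])
    row_of = {rec_id: k for k, rec_id in enumerate(alignment.ids)}
    members = {sp: [row_of[i] for i in species_map.members(sp)] for sp in species}

    # per species: counts of each base per column, and non-base counts
    base_counts = {}
    nonbase = {}
    for sp, rows in members.items():
        sub = codes[rows]
        base_counts[sp] = np.stack([(sub == b).sum(axis=0) for b in range(4)])
        nonbase[sp] = (sub == 255).sum(axis=0)

    positions: list[DiagnosticPosition] = []
    length = alignment.length
    bases = "ACGT"
    for col in range(length):
        observed = {
            sp: frozenset(bases[b] for b in range(4) if base_counts[sp][b, col] > 0)
            for sp in species
        }
        for sp in species:
            n = len(members[sp])
            if nonbase[sp][col] > tolerance * n:
                continue
            present = [b for b in range(4) if base_counts[sp][b, col] > 0]
            if len(present) != 1:
                continue
            b = present[0]
            state = bases[b]
            if any(state in observed[other] for other in species if other != sp):
                continue
            positions.append(DiagnosticPosition(col, sp, state, observed))
    return DiagnosticTable(positions, tuple(species), length)


@dataclass(frozen=True)
class PlacementResult:
    query_id: str
    verdict: str
    species: str | None
    counts: Mapping[str, tuple[int, int, int]]  # species -> (covered, mismatches, uncertain)
    mismatch_columns: tuple[int, ...]
    uncertain_columns: tuple[int, ...]

    def covered(self, species: str) -> int:
        return self.counts[species][0]

    def mismatches(self, species: str) -> int:
        return self.counts[species][1]

    def uncertain(self, species: str) -> int:
        return self.counts[species][2]


def place_sequence(
    query: SequenceRecord,
    table: DiagnosticTable,
    min_covered: int = 3,
) -> PlacementResult:
    """Place an aligned query by its states at the diagnostic columns.

    Verdict rule (deterministic, order-independent):
    assigned(S)  — S is the unique mismatch-free species and its covered
                   diagnostic positions number >= ``min_covered``;
    uncertain    — a unique mismatch-free species exists but is short of
                   coverage, or >= 2 species tie at zero mismatches;
    conflicting  — every species has at least one mismatch.
    """
    if len(table) == 0:
        raise ValueError("empty diagnostic table")
    if len(query.seq) != table.n_columns:
        raise ValueError(
            f"query {query.id!r} has {len(query.seq)} columns, reference has {table.n_columns}"
        )
    stats = {sp: [0, 0, 0] for sp in table.species}  # covered, mismatches, uncertain
    mismatch_cols: list[int] = []
    uncertain_cols: list[int] = []
    for pos in table.positions:
        ch = query.seq[pos.column]
        if ch in IUPAC_BASES:
            stats[pos.species][0] += 1
            if ch != pos.state:
                stats[pos.species][1] += 1
                mismatch_cols.append(pos.column)
        elif ch in IUPAC_AMBIGUITIES:
            stats[pos.species][2] += 1
            uncertain_cols.append(pos.column)
        # gaps / '?' are uncovered: counted nowhere

    zero_mm = [sp for sp in table.species if stats[sp][1] == 0]
    if not zero_mm:
        verdict, species = CONFLICTING, None
    elif len(zero_mm) == 1:
        sp = zero_mm[0]
        if stats[sp][0] >= min_covered:
            verdict, species = ASSIGNED, sp
        else:
            verdict, species = UNCERTAIN, sp
    else:
        verdict, species = UNCERTAIN, None
    return PlacementResult(
        query_id=query.id,
        verdict=verdict,
        species=species,
        counts={sp: tuple(v) for sp, v in stats.items()},
        mismatch_columns=tuple(sorted(set(mismatch_cols))),
        uncertain_columns=tuple(sorted(set(uncertain_cols))),
    )


def placements_to_dataframe(results: list[PlacementResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.query_id,
                "verdict": r.verdict,
                "species": r.species or "",
                "mismatch_columns_1based": ",".join(str(c + 1) for c in r.mismatch_columns),
                "uncertain_columns_1based": ",".join(str(c + 1) for c in r.uncertain_columns),
                **{
                    f"{sp}:covered/mismatch/uncertain": "/".join(map(str, r.counts[sp]))
                    for sp in sorted(r.counts)
                },
            }
        )
    return pd.DataFrame(rows)


class NoAnchorError(ValueError):
    """No reference shares a k-mer with the query; it cannot be threaded."""


def _kmers(seq: str, k: int) -> set[str]:
    s = seq.replace("-", "").replace("?", "")
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def align_query(
    query: SequenceRecord,
    alignment: Alignment,
    k: int = 8,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> SequenceRecord:
    """Thread an unaligned query onto the reference columns.

    The closest reference is chosen by shared ``k``-mer count (ties break
    on reference order); the query is globally aligned to its ungapped
    residues and mapped back to alignment columns.  Columns the query does
    not reach are ``?``; columns it spans but deletes are ``-``.  Query
    insertions relative to the reference cannot be represented on the fixed
    column set and are dropped.
    """
    if not query.seq:
        raise ValueError("empty query")
    qk = _kmers(query.seq, k)
    best_id, best_shared = None, 0
    for rec in alignment.records:
        shared = len(qk & _kmers(rec.seq, k))
        if shared > best_shared:
            best_id, best_shared = rec.id, shared
    if best_id is None:
        raise NoAnchorError(f"query {query.id!r} shares no {k}-mer with any reference")
    ref = alignment.get(best_id)
    ref_cols = [i for i, ch in enumerate(ref.seq) if ch not in GAP_CHARS]
    ref_ungapped = "".join(ref.seq[i] for i in ref_cols)
    q_ungapped = query.seq.replace("-", "").replace("?", "")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free terminal overhangs: a fragment must thread contiguously instead
    # of paying end gaps (which ties contiguous and split placements)
    aligner.end_gap_score = 0.0
    aln = aligner.align(ref_ungapped, q_ungapped)[0]

    out = ["?"] * alignment.length
    placed: list[int] = []
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            col = ref_cols[t0 + off]
            out[col] = q_ungapped[q0 + off]
            placed.append(col)
    if placed:
        lo, hi = min(placed), max(placed)
        for col in range(lo, hi + 1):
            if out[col] == "?":
                out[col] = "-"
    return SequenceRecord(query.id, "".join(out), description=query.description,
                          source=query.source)


@dataclass(frozen=True)
class QualityFlags:
    record_id: str
    flags: frozenset[str]
    ambiguity_fraction: float
    region_coverage: Mapping[str, float]

    def has(self, flag: str) -> bool:
        return flag in self.flags


def consensus_sequence(alignment: Alignment, ids: list[str] | None = None) -> str:
    """Majority unambiguous base per column (ties break alphabetically);
    columns with no base at all become 'N'."""
    sub = alignment if ids is None else alignment.subset(ids)
    codes = np.vstack([encode(r.seq) for r in sub.records])
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    best = counts.argmax(axis=0)  # argmax takes the first (alphabetical) max
    has_base = counts.sum(axis=0) > 0
    bases = np.array(list("ACGT"))
    out = np.where(has_base, bases[best], "N")
    return "".join(out)


def screen_quality(
    record: SequenceRecord,
    region_map: Mapping[str, tuple[int, int]],
    consensus: str | None = None,
    max_ambiguity_fraction: float = 0.02,
    domain_region: str = "5.8S",
    min_domain_deviations: int = 2,
) -> QualityFlags:
    """Flag short (single-spacer), ambiguity-laden and domain-deviant records.

    partial:ITS1 / partial:ITS2 — exactly one spacer covered >= 50 % while
    the other is < 10 %; high_ambiguity — IUPAC-ambiguity fraction of the
    present residues above ``max_ambiguity_fraction``; domain_deviant —
    >= ``min_domain_deviations`` unambiguous differences from the reference
    consensus inside the conserved ``domain_region``.
    """
    seq = record.seq
    coverage: dict[str, float] = {}
    for name, (start, end) in region_map.items():
        chunk = seq[start:end]
        present = sum(1 for c in chunk if c not in GAP_CHARS)
        coverage[name] = present / (end - start)

    flags: set[str] = set()
    its1 = coverage.get("ITS1", 0.0)
    its2 = coverage.get("ITS2", 0.0)
    if its1 >= 0.5 and its2 < 0.1:
        flags.add(FLAG_PARTIAL_ITS1)
    elif its2 >= 0.5 and its1 < 0.1:
        flags.add(FLAG_PARTIAL_ITS2)
    else:
        flags.add(FLAG_FULL_LENGTH)

    present_total = sum(1 for c in seq if c not in GAP_CHARS)
    n_ambig = sum(1 for c in seq if c in IUPAC_AMBIGUITIES)
    ambiguity_fraction = n_ambig / present_total if present_total else 0.0
    if ambiguity_fraction > max_ambiguity_fraction:
        flags.add(FLAG_HIGH_AMBIGUITY)

    if consensus is not None and domain_region in region_map:
        start, end = region_map[domain_region]
        deviations = sum(
            1
            for i in range(start, end)
            if seq[i] in IUPAC_BASES
            and consensus[i] in IUPAC_BASES
            and seq[i] != consensus[i]
        )
        if deviations >= min_domain_deviations:
            flags.add(FLAG_DOMAIN_DEVIANT)

    return QualityFlags(record.id, frozenset(flags), ambiguity_fraction, coverage)


def quality_to_dataframe(flags: list[QualityFlags]) -> pd.DataFrame:
    rows = []
    for f in flags:
        rows.append(
            {
                "id": f.record_id,
                "flags": ",".join(sorted(f.flags)),
                "ambiguity_fraction": round(f.ambiguity_fraction, 6),
                **{f"coverage:{r}": round(c, 4) for r, c in sorted(f.region_coverage.items())},
            }
        )
    return pd.DataFrame(rows)
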