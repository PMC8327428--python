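"""Sequence, alignment and metadata I/O with validation.

FASTA parsing goes through Biopython; this module adds the checks the rest
of the pipeline relies on: a strict IUPAC nucleotide alphabet, unique
record ids, equal-length alignments, and region annotations in 0-based
half-open coordinates.

Two "no information" characters are kept distinct in files for provenance:
``-`` marks an alignment gap, ``?`` marks residues that are missing because
a record was truncated to a sub-region.  Downstream distance and diagnostic
code treats both (and every IUPAC ambiguity code) as "no usable base".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

IUPAC_BASES = frozenset("ACGT")
IUPAC_AMBIGUITIES = frozenset("RYSWKMBDHVN")
GAP_CHARS = frozenset("-?")
ALPHABET = IUPAC_BASES | IUPAC_AMBIGUITIES | GAP_CHARS

#: residue sets denoted by each IUPAC code
IUPAC_CODE_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ROLE_REFERENCE = "reference"
ROLE_QUERY = "query"


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with a unique id.

    ``source`` records provenance (author | GenBank | UNITE | BOLD |
    synthetic) and is never interpreted.  ``description`` is the FASTA
    header text after the first whitespace, preserved opaquely.
    """

    id: str
    seq: str
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        for offset, ch in enumerate(self.seq):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into validated records (uppercased residues).

    Raises ``ValueError`` on duplicate ids or illegal residues; an empty
    file yields an empty list with a logged warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), description=desc))
    if not records:
        logger.warning("no sequence records found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA; lossless round trip on (id, residues)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


@dataclass
class Alignment:
    """Equal-length sequence records plus a region annotation.

    ``region_map`` maps region names (ITS1, 5.8S, ITS2, ...) to 0-based
    half-open column intervals.  Intervals must lie within the alignment
    and must not overlap.
    """

    records: list[SequenceRecord]
    region_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            expect = len(self.records[0])
            bad = [r.id for r in self.records if len(r) != expect]
            raise ValueError(f"ragged alignment; offending ids: {', '.join(bad)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in alignment: {', '.join(dup)}")
        length = self.length
        spans = []
        for name, (start, end) in self.region_map.items():
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"region {name!r} interval [{start}, {end}) outside alignment of length {length}"
                )
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"regions {n1!r} and {n2!r} overlap")
        self._index = {r.id: i for i, r in enumerate(self.records)}

    @property
    def length(self) -> int:
        return len(self.records[0]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def get(self, rec_id: str) -> SequenceRecord:
        return self.records[self._index[rec_id]]

    def to_matrix(self) -> np.ndarray:
        """Residues as an (n, L) uint8 array of ASCII codes."""
        if not self.records:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([
            np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8) for r in self.records
        ])

    def region_slice(self, name: str) -> slice:
        start, end = self.region_map[name]
        return slice(start, end)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment([self.get(i) for i in ids], dict(self.region_map))


def validate_alignment(
    records: Sequence[SequenceRecord],
    region_map: Mapping[str, tuple[int, int]] | None = None,
) -> Alignment:
    """Check equal lengths and region bounds; return the Alignment."""
    return Alignment(list(records), dict(region_map or {}))


@dataclass(frozen=True)
class SampleInfo:
    species: str
    role: str = ROLE_REFERENCE
    flags: tuple[str, ...] = ()


@dataclass
class SpeciesMap:
    """sequence id -> species label, with a reference/query role per id."""

    samples: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        for rec_id, info in self.samples.items():
            if info.role not in (ROLE_REFERENCE, ROLE_QUERY):
                raise ValueError(f"{rec_id!r}: unknown role {info.role!r}")
            if info.role == ROLE_REFERENCE and (not info.species or info.species == "unknown"):
                raise ValueError(f"reference record {rec_id!r} lacks a species label")

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.samples

    def species_of(self, rec_id: str) -> str:
        return self.samples[rec_id].species

    def role_of(self, rec_id: str) -> str:
        return self.samples[rec_id].role

    @property
    def reference_ids(self) -> list[str]:
        return [i for i, s in self.samples.items() if s.role == ROLE_REFERENCE]

    @property
    def query_ids(self) -> list[str]:
        return [i for i, s in self.samples.items() if s.role == ROLE_QUERY]

    @property
    def species_labels(self) -> list[str]:
        return sorted({s.species for s in self.samples.values() if s.role == ROLE_REFERENCE})

    def members(self, species: str) -> list[str]:
        """Reference ids carrying the given species label."""
        out = [i for i, s in self.samples.items()
               if s.role == ROLE_REFERENCE and s.species == species]
        if not out:
            raise KeyError(f"species {species!r} has no reference members")
        return out


METADATA_COLUMNS = ("id", "species", "role", "flags")


def read_metadata(path: str | Path, alignment: Alignment | None = None) -> SpeciesMap:
    """Read the tab-separated metadata table (id, species, role[, flags]).

    Rows whose id is absent from ``alignment`` (when given) are excluded
    with a warning; a reference row without a species label is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"id", "species", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks required columns: {sorted(missing)}")
    samples: dict[str, SampleInfo] = {}
    for row in df.itertuples(index=False):
        rec_id = row.id
        if alignment is not None and rec_id not in alignment:
            logger.warning("metadata id %r not in alignment; row excluded", rec_id)
            continue
        if rec_id in samples:
            raise ValueError(f"duplicate metadata id {rec_id!r}")
        flags = tuple(f for f in str(getattr(row, "flags", "")).split(",") if f)
        species = row.species or "unknown"
        samples[rec_id] = SampleInfo(species=species, role=row.role, flags=flags)
    return SpeciesMap(samples)


def write_metadata(species_map: SpeciesMap, path: str | Path) -> None:
    rows = [
        {"id": i, "species": s.species, "role": s.role, "flags": ",".join(s.flags)}
        for i, s in species_map.samples.items()
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)
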