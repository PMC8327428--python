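"""Pairwise p-distances with explicit overlap, gap and ambiguity rules.

The distance is the uncorrected proportion of mismatching sites among the
columns where *both* sequences carry an unambiguous base (A, C, G or T).
Gaps, ``?`` and every IUPAC ambiguity code exclude the column for that pair
(pairwise deletion).  A pair whose comparable overlap falls below
``min_overlap`` sites gets no distance at all — an explicit missing state,
which downstream clustering treats as "no edge", never as 0 or 1.

UNITE-style thresholds are similarity complements, so similarity = 1 - d
and a "0.5 %" distance threshold equals 99.5 % identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Alignment, SequenceRecord

DEFAULT_MIN_OVERLAP = 100

# ACGT -> 0..3, everything else (ambiguities, gaps, '?') -> 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes: A..T -> 0..3, non-base -> 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pairwise_p_distance(
    a: str | SequenceRecord,
    b: str | SequenceRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float | None:
    """p-distance between two aligned sequences, or None if overlap is short.

    Raises ``ValueError`` on unequal lengths.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    ea, eb = encode(sa), encode(sb)
    both = (ea < 4) & (eb < 4)
    n = int(both.sum())
    if n < min_overlap:
        return None
    mismatches = int(((ea != eb) & both).sum())
    return mismatches / n


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with an explicit missing state.

    ``values`` holds distances in [0, 1] with ``nan`` for missing pairs;
    ``n_compared`` the per-pair comparable-site counts.
    """

    ids: list[str]
    values: np.ndarray
    n_compared: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float | None:
        v = self.values[self._index[a], self._index[b]]
        return None if np.isnan(v) else float(v)

    def is_missing(self, a: str, b: str) -> bool:
        return bool(np.isnan(self.values[self._index[a], self._index[b]]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.6f")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance matrix; missing pairs written as -1.0
        (PHYLIP has no missing state; the sentinel is documented here)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, rec_id in enumerate(self.ids):
                row = np.where(np.isnan(self.values[i]), -1.0, self.values[i])
                fh.write(rec_id[:50].ljust(50))
                fh.write("  ".join(f"{v:.6f}" for v in row))
                fh.write("\n")


def distance_matrix(
    alignment: Alignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs p-distance matrix; symmetric by construction, zero diagonal."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    mat = alignment.to_matrix()
    codes = _ENCODE[mat]
    valid = codes < 4
    n = len(alignment)
    values = np.zeros((n, n), dtype=float)
    compared = np.zeros((n, n), dtype=int)
    np.fill_diagonal(compared, valid.sum(axis=1))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            compared[i, j] = compared[j, i] = nc
            if nc < min_overlap:
                values[i, j] = values[j, i] = np.nan
            else:
                mm = int(((codes[i] != codes[j]) & both).sum())
                values[i, j] = values[j, i] = mm / nc
    return DistanceMatrix(list(alignment.ids), values, compared, min_overlap)
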