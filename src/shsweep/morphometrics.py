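"""Micro-morphological measurement summaries in taxonomic notation.

Species descriptions report spore and cystidia dimensions as
``(min–)low–mean–high(–max)``, e.g. ``(7.1–)7.5–8.0–8.5(–9.4)`` µm, with
the spore length/width quotient Q summarised the same way at two decimals.
Here ``low``/``high`` are the sample mean ∓ one sample (n−1) standard
deviation, clamped into [min, max] — the convention of the description
standard this notation follows; 5th/95th percentiles are available as an
alternative interpretation via ``spread="percentile"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

DASH = "–"  # en dash, as printed in descriptions

_DASH_CLASS = r"[–—−-]"  # en/em dash, minus, hyphen
_NUM = r"(\d+(?:\.\d+)?)"
_SUMMARY_RE = re.compile(
    rf"^\(\s*{_NUM}\s*{_DASH_CLASS}\s*\)\s*{_NUM}\s*{_DASH_CLASS}\s*{_NUM}"
    rf"\s*{_DASH_CLASS}\s*{_NUM}\s*\(\s*{_DASH_CLASS}\s*{_NUM}\s*\)$"
)


@dataclass(frozen=True)
class MeasurementSummary:
    """Five-number description summary; all values rounded to ``rounding``."""

    minimum: float
    low: float
    mean: float
    high: float
    maximum: float
    n: int | None = None
    unit: str = "µm"
    rounding: float = 0.1

    def __post_init__(self) -> None:
        seq = (self.minimum, self.low, self.mean, self.high, self.maximum)
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"summary fields not ordered: {seq}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.low, self.mean, self.high, self.maximum)


def _round_step(value: float, step: float) -> float:
    decimals = max(0, int(round(-np.log10(step))))
    return float(np.round(np.round(value / step) * step, decimals))


def summarize(
    values: Sequence[float],
    rounding: float = 0.1,
    unit: str = "µm",
    spread: str = "sd",
) -> MeasurementSummary:
    """Summarise measurements as (min–)low–mean–high(–max).

    ``spread="sd"`` (default): low/high = mean ∓ 1 sample SD; ``"percentile"``:
    5th/95th percentiles.  Requires n >= 2 positive values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 measurements, got {arr.size}")
    if (arr <= 0).any():
        raise ValueError("measurements must be positive")
    mean = float(arr.mean())
    if spread == "sd":
        sd = float(arr.std(ddof=1))
        low, high = mean - sd, mean + sd
    elif spread == "percentile":
        low, high = (float(v) for v in np.percentile(arr, [5, 95]))
    else:
        raise ValueError(f"unknown spread convention {spread!r}")
    lo_obs, hi_obs = float(arr.min()), float(arr.max())
    low = max(low, lo_obs)
    high = min(high, hi_obs)
    return MeasurementSummary(
        minimum=_round_step(lo_obs, rounding),
        low=_round_step(low, rounding),
        mean=_round_step(mean, rounding),
        high=_round_step(high, rounding),
        maximum=_round_step(hi_obs, rounding),
        n=int(arr.size),
        unit=unit,
        rounding=rounding,
    )


def q_summary(
    lengths: Sequence[float],
    widths: Sequence[float],
    rounding: float = 0.01,
    spread: str = "sd",
) -> MeasurementSummary:
    """Summary of the element-wise quotient Q = length/width (paired)."""
    l = np.asarray(list(lengths), dtype=float)
    w = np.asarray(list(widths), dtype=float)
    if l.shape != w.shape:
        raise ValueError(f"unpaired input: {l.size} lengths vs {w.size} widths")
    if (w <= 0).any():
        raise ValueError("widths must be positive")
    return summarize(l / w, rounding=rounding, unit="", spread=spread)


def format_summary(s: MeasurementSummary, always_parenthesize: bool = True) -> str:
    """Render ``(min–)low–mean–high(–max)``.

    With ``always_parenthesize=False`` the parenthetical extremes are
    omitted when they equal the adjacent inner bound.
    """
    decimals = max(0, int(round(-np.log10(s.rounding))))
    f = lambda v: f"{v:.{decimals}f}"
    left = f"({f(s.minimum)}{DASH})" if always_parenthesize or s.minimum != s.low else ""
    right = f"({DASH}{f(s.maximum)})" if always_parenthesize or s.maximum != s.high else ""
    return f"{left}{f(s.low)}{DASH}{f(s.mean)}{DASH}{f(s.high)}{right}"


def parse_summary(
    text: str, unit: str = "µm", rounding: float | None = None
) -> MeasurementSummary:
    """Parse the five-number notation back to a summary (n is unknown).

    ``rounding`` is inferred from the printed decimals when not given.
    """
    m = _SUMMARY_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse measurement summary {text!r}")
    nums = [float(g) for g in m.groups()]
    if rounding is None:
        decimals = max((len(g.split(".")[1]) if "." in g else 0) for g in m.groups())
        rounding = float(10.0 ** -decimals)
    return MeasurementSummary(*nums, n=None, unit=unit, rounding=rounding)
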