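"""Sliding-window GC analysis: the HGT screen.

A horizontally transferred operon tends to retain the donor's base
composition; the screen contrasts the operon span's GC content with ~10-kb
flanking regions using 500-bp windows.  All deltas are reported in
percentage points, matching the ">=7% higher" reading of the published
profiles.

Ambiguous bases (anything outside ACGT, case-insensitive) are excluded from
both the numerator and the denominator by default; a config flag counts them
toward the denominator instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GCProfile",
    "RegionContrast",
    "gc_fraction",
    "window_gc",
    "region_contrast",
    "subregion_contrast",
]


def _base_arrays(sequence: str):
    arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_at = (arr == b"A") | (arr == b"T")
    return is_gc, is_at


def gc_fraction(sequence: str, count_ambiguous: bool = False) -> float:
    """GC fraction of a sequence; ambiguous bases excluded by default."""
    if not sequence:
        raise ValueError("empty sequence")
    is_gc, is_at = _base_arrays(sequence)
    denom = len(sequence) if count_ambiguous else int(is_gc.sum() + is_at.sum())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return float(is_gc.sum()) / denom


@dataclass
class GCProfile:
    region_id: str
    window_size: int
    step: int
    windows: list[tuple[int, float]] = field(default_factory=list)
    region_means: dict[str, float] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["start", "gc"])


def window_gc(
    sequence: str,
    window_size: int = 500,
    step: int = 1,
    region_id: str = "",
    count_ambiguous: bool = False,
) -> GCProfile:
    """GC fraction in sliding windows of ``window_size`` bp.

    Window starts run 0, step, ... up to ``len - window_size`` inclusive.
    A window larger than the sequence is an error.
    """
    n = len(sequence)
    if window_size < 1 or window_size > n:
        raise ValueError(f"window_size {window_size} outside [1, {n}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    is_gc, is_at = _base_arrays(sequence)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_known = np.concatenate([[0], np.cumsum(is_gc | is_at)])
    windows = []
    for start in range(0, n - window_size + 1, step):
        end = start + window_size
        gc = cum_gc[end] - cum_gc[start]
        known = (
            window_size if count_ambiguous else cum_known[end] - cum_known[start]
        )
        windows.append((start, float(gc) / known if known else float("nan")))
    return GCProfile(
        region_id=region_id, window_size=window_size, step=step, windows=windows
    )


@dataclass
class RegionContrast:
    operon_gc: float
    upstream_gc: float | None
    downstream_gc: float | None
    delta_points: float
    upstream_truncated: bool
    downstream_truncated: bool

    def to_dict(self) -> dict:
        return {
            "operon_gc": self.operon_gc,
            "upstream_gc": self.upstream_gc,
            "downstream_gc": self.downstream_gc,
            "delta_points": self.delta_points,
            "upstream_truncated": self.upstream_truncated,
            "downstream_truncated": self.downstream_truncated,
        }


def region_contrast(
    sequence: str,
    operon_span: tuple[int, int],
    flank: int = 10000,
    count_ambiguous: bool = False,
) -> RegionContrast:
    """Mean GC of the operon span vs its two flanks, and their difference.

    ``operon_span`` is 0-based half-open on ``sequence``.  Flanks are
    truncated at the contig ends (and flagged); a missing flank simply drops
    out of the flank mean.  ``delta_points`` = GC(operon) - mean(flank GCs),
    in percentage points.
    """
    start, end = operon_span
    if not (0 <= start < end <= len(sequence)):
        raise ValueError(f"span {operon_span} outside sequence [0, {len(sequence)})")
    operon = gc_fraction(sequence[start:end], count_ambiguous)
    up_start = max(0, start - flank)
    down_end = min(len(sequence), end + flank)
    upstream = (
        gc_fraction(sequence[up_start:start], count_ambiguous)
        if start > up_start
        else None
    )
    downstream = (
        gc_fraction(sequence[end:down_end], count_ambiguous)
        if down_end > end
        else None
    )
    flank_values = [v for v in (upstream, downstream) if v is not None]
    if not flank_values:
        raise ValueError("no flanking sequence on either side of the span")
    delta = 100.0 * (operon - sum(flank_values) / len(flank_values))
    return RegionContrast(
        operon_gc=operon,
        upstream_gc=upstream,
        downstream_gc=downstream,
        delta_points=delta,
        upstream_truncated=(start - up_start) < flank,
        downstream_truncated=(down_end - end) < flank,
    )


def subregion_contrast(
    sequence: str,
    spans: dict[str, tuple[int, int]],
    count_ambiguous: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-span mean GC plus pairwise deltas in percentage points.

    Used for within-operon contrasts such as the core operon (cyp112->ks)
    against the lower-GC ggps2, or an elevated idi fragment 3' of ks.
    Overlapping spans are allowed; zero-length spans are errors.
    """
    gc: dict[str, float] = {}
    for name, (start, end) in spans.items():
        if not (0 <= start < end <= len(sequence)):
            raise ValueError(f"span {name}={start, end} invalid for length {len(sequence)}")
        gc[name] = gc_fraction(sequence[start:end], count_ambiguous)
    means = pd.DataFrame(
        [{"span": name, "gc": gc[name]} for name in spans]
    )
    names = list(spans)
    deltas = pd.DataFrame(
        [
            {
                "span_a": a,
                "span_b": b,
                "delta_points": 100.0 * (gc[a] - gc[b]),
            }
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
    )
    return means, deltas
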