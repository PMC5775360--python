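"""Sliding-window diversity profiling and divergence-hotspot extraction.

Windows slide over alignment columns (gapped columns count toward window
span; statistics use the analyzed columns only). A window is selected as
highly variable when its polymorphic-site count S strictly exceeds
mean(S) + k_sd * sd(S) over all windows (population sd by default);
overlapping or exactly abutting selected windows merge into hotspot
regions, which are then named from the reference annotation — a gene name
for regions inside one gene (suffixed a, b, ... when one gene yields
several disjoint regions), or flanking/contained genes joined by '-' for
intergenic spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import AlignmentMatrix, GeneFeature
from .divergence import diversity_stats
from .ssr_scan import _ungapped_to_columns

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowParams:
    window_length: int = 600
    step: int = 200
    k_sd: float = 2.0
    population_sd: bool = True

    def __post_init__(self) -> None:
        if self.window_length < 100:
            raise ValueError("window_length below 100 columns")
        if self.step > self.window_length:
            raise ValueError("step larger than window_length")


@dataclass
class WindowStat:
    start: int
    end: int
    S: int
    pi: float
    truncated: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class HotspotRegion:
    """A merged above-threshold interval with marker statistics."""

    columns: tuple[int, int]       # alignment interval
    name: str
    ref_interval: Optional[tuple[int, int]]  # on the reference genome
    length: int                    # alignment columns
    S: int
    PI: int
    pi: float


def window_scan(alignment: AlignmentMatrix, params: WindowParams | None = None) -> list[WindowStat]:
    """Per-window S and π at fixed column starts 0, step, 2*step, ...

    The trailing windows shorter than window_length are included and
    flagged truncated. Windows with no analyzable column get S=0, π=0.
    """
    params = params or WindowParams()
    L = alignment.length
    if L < params.window_length:
        log.warning("alignment (%d cols) shorter than window length %d", L, params.window_length)
    stats: list[WindowStat] = []
    n_trunc = 0
    starts = [0] if L <= params.window_length else range(0, L - 1, params.step)
    for start in starts:
        end = min(start + params.window_length, L)
        try:
            rs = diversity_stats(alignment, np.arange(start, end))
            s_, pi_ = rs.S, rs.pi
        except ValueError:  # window entirely gapped
            s_, pi_ = 0, 0.0
        trunc = end - start < params.window_length
        n_trunc += trunc
        stats.append(WindowStat(start, end, s_, pi_, truncated=trunc))
    if n_trunc:
        log.info("window_scan: %d truncated trailing window(s)", n_trunc)
    return stats


def select_hotspots(
    windows: list[WindowStat], params: WindowParams | None = None
) -> list[tuple[int, int]]:
    """Merged column intervals of windows with S > mean(S) + k_sd * sd(S)."""
    params = params or WindowParams()
    if len(windows) < 2:
        raise ValueError("hotspot threshold undefined for fewer than 2 windows")
    s_vals = np.array([w.S for w in windows], dtype=float)
    sd = s_vals.std(ddof=0 if params.population_sd else 1)
    threshold = s_vals.mean() + params.k_sd * sd
    selected = [w for w in windows if w.S > threshold]
    merged: list[list[int]] = []
    for w in sorted(selected, key=lambda w: w.start):
        if merged and w.start <= merged[-1][1]:  # overlap or exact abutment
            merged[-1][1] = max(merged[-1][1], w.end)
        else:
            merged.append([w.start, w.end])
    return [(a, b) for a, b in merged]


def _columns_to_ref(columns: tuple[int, int], colmap: np.ndarray) -> tuple[int, int]:
    """Map an alignment-column interval to ungapped reference coordinates."""
    lo, hi = columns
    inside = np.searchsorted(colmap, [lo, hi])
    return int(inside[0]), int(inside[1])


def annotate_hotspots(
    intervals: list[tuple[int, int]],
    alignment: AlignmentMatrix,
    features: list[GeneFeature],
    reference_row: str,
) -> list[HotspotRegion]:
    """Name and summarize merged hotspot intervals against the reference.

    Statistics (length, S, PI, π) are computed on each merged interval's
    columns, not per window.
    """
    if reference_row not in alignment.ids:
        raise KeyError(f"reference row {reference_row!r} not in alignment")
    colmap = _ungapped_to_columns(alignment.row(reference_row))
    named: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    for iv in intervals:
        ref_iv = _columns_to_ref(iv, colmap)
        named.append((iv, ref_iv, _name_interval(ref_iv, features)))
    # disambiguate several disjoint regions named after the same single gene
    from collections import Counter

    counts = Counter(name for _, _, name in named if "-" not in name)
    suffix_state: dict[str, int] = {}
    regions: list[HotspotRegion] = []
    for iv, ref_iv, name in named:
        if "-" not in name and counts[name] > 1:
            idx = suffix_state.get(name, 0)
            suffix_state[name] = idx + 1
            name = f"{name}{chr(ord('a') + idx)}"
        rs = diversity_stats(alignment, np.arange(iv[0], iv[1]))
        regions.append(
            HotspotRegion(
                columns=iv,
                name=name,
                ref_interval=ref_iv,
                length=iv[1] - iv[0],
                S=rs.S,
                PI=rs.PI,
                pi=rs.pi,
            )
        )
    return regions


def _name_interval(ref_iv: tuple[int, int], features: list[GeneFeature]) -> str:
    lo, hi = ref_iv
    overlapped = []
    for f in features:
        s, e = f.span
        if max(lo, s) < min(hi, e):
            overlapped.append((s, f.name))
    if len(overlapped) == 1:
        s, e = next(f.span for f in features if f.name == overlapped[0][1])
        if s <= lo and hi <= e:
            return overlapped[0][1]  # fully inside one gene
    parts: list[str] = []
    left = [(e, f.name) for f in features for (s, e) in [f.span] if e <= lo]
    right = [(s, f.name) for f in features for (s, e) in [f.span] if s >= hi]
    if left:
        parts.append(max(left)[1])
    parts.extend(name for _, name in sorted(overlapped))
    if right:
        parts.append(min(right)[1])
    seen: list[str] = []
    for p in parts:
        if p not in seen:
            seen.append(p)
    return "-".join(seen) if seen else "unannotated"
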