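"""Maximal large-repeat detection at bounded Hamming distance.

Four match types are found between segments of one (linear) genome:
forward (F, direct copy), reverse (R, match to the reversed segment),
complement (C, match to the complemented segment) and palindromic
(P, match to the reverse complement). A hit is a maximal pair: extending
it on either flank would exceed the mismatch budget or leave the sequence.

The finder enumerates, for every alignment diagonal of the sequence
against its transformed self, all maximal windows containing at most
``max_mismatch`` mismatches — an exact formulation of REPuter-style
mismatch repeats, without its E-value statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import comp_arr, encode
from .core_io import ReportTable, SeqRecord
from .quadripartite import RegionPartition

REPEAT_TYPES = ("F", "R", "C", "P")
LENGTH_BINS = ((30, 39), (40, 49), (50, 59), (60, None))


@dataclass(frozen=True)
class RepeatParams:
    min_len: int = 30
    max_mismatch: int = 3
    types: tuple[str, ...] = REPEAT_TYPES

    def __post_init__(self) -> None:
        if self.min_len < 8:
            raise ValueError("min_len below 8 (seed degeneracy)")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        bad = set(self.types) - set(REPEAT_TYPES)
        if bad:
            raise ValueError(f"unknown repeat types {bad}")


@dataclass(frozen=True)
class RepeatHit:
    """A maximal repeat pair; copy intervals are 0-based half-open."""

    type: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    length: int
    mismatches: int


@dataclass
class RepeatLocus:
    """Hits sharing (type, length, region assignment), collapsed."""

    type: str
    length: int
    regions: tuple[str, str]
    members: list[RepeatHit] = field(default_factory=list)

    @property
    def member_count(self) -> int:
        return len(self.members)


def _maximal_windows(mism: np.ndarray, k: int, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal (start, end, n_mismatch) windows with <= k mismatches, >= min_len.

    ``mism`` is a boolean array along one diagonal. Windows run between
    consecutive mismatches: with mismatch positions p_1..p_M (padded by -1
    and len), each window spans (p_i + 1, p_{i+k+1} - 1) and holds exactly
    k interior mismatches, except when M <= k (whole diagonal, M mismatches).
    """
    L = len(mism)
    pos = np.flatnonzero(mism)
    M = len(pos)
    if M <= k:
        return [(0, L, M)] if L >= min_len else []
    padded = np.concatenate(([-1], pos, [L]))
    starts = padded[: M - k + 1] + 1
    ends = padded[k + 1 :]
    keep = np.flatnonzero(ends - starts >= min_len)
    return [(int(starts[i]), int(ends[i]), k) for i in keep]


def _candidate_diagonals(s_bytes: bytes, t_bytes: bytes, q: int) -> set[int]:
    """Diagonals d where s and t share an exact q-mer (s[i:i+q] == t[i+d:i+d+q]).

    By pigeonhole, any window of length >= min_len with <= k mismatches
    contains an exact run of >= ceil((min_len - k) / (k + 1)) positions, so
    seeding with q no larger than that bound misses nothing.
    """
    index: dict[bytes, list[int]] = {}
    for i in range(len(s_bytes) - q + 1):
        index.setdefault(s_bytes[i : i + q], []).append(i)
    diagonals: set[int] = set()
    for j in range(len(t_bytes) - q + 1):
        for i in index.get(t_bytes[j : j + q], ()):
            diagonals.add(j - i)
    return diagonals


def find_repeats(record: SeqRecord, params: RepeatParams | None = None) -> list[RepeatHit]:
    """All maximal repeat pairs of the requested types on a linear sequence.

    N positions never match anything (another N included), so repeats
    cannot extend through undetermined sequence.
    """
    params = params or RepeatParams()
    if "-" in record.seq:
        raise ValueError(f"record {record.id!r}: gap characters in repeat scan input")
    s = encode(record.seq)
    n = len(s)
    is_n = s == ord("N")
    hits: set[RepeatHit] = set()
    k = params.max_mismatch
    q_bound = -(-(params.min_len - k) // (k + 1))  # ceil
    seed_q = min(12, q_bound) if q_bound >= 6 else None

    def add(type_: str, c1: tuple[int, int], c2: tuple[int, int], mm: int) -> None:
        if c1 == c2:
            return
        if c2 < c1:
            c1, c2 = c2, c1
        hits.add(RepeatHit(type_, c1, c2, c1[1] - c1[0], mm))

    def diagonals(t: np.ndarray, lo_d: int, hi_d: int) -> list[int]:
        if seed_q is None:
            return list(range(lo_d, hi_d))
        cand = _candidate_diagonals(s.tobytes(), t.tobytes(), seed_q)
        return sorted(d for d in cand if lo_d <= d < hi_d)

    def scan_parallel(type_: str, t: np.ndarray, t_is_n: np.ndarray) -> None:
        # copy1 at i in s, copy2 at i+d in t; same orientation; d > 0 counts
        # each unordered pair once
        for d in diagonals(t, 1, n - params.min_len + 1):
            a = s[: n - d]
            b = t[d:]
            mism = (a != b) | is_n[: n - d] | t_is_n[d:]
            for (ws, we, mm) in _maximal_windows(mism, k, params.min_len):
                add(type_, (ws, we), (ws + d, we + d), mm)

    def scan_anti(type_: str, t: np.ndarray, t_is_n: np.ndarray) -> None:
        # copy1 at i in s matches t at i+d; t position q maps to s position n-1-q
        for d in diagonals(t, -(n - 1), n):
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < params.min_len:
                continue
            a = s[lo:hi]
            b = t[lo + d : hi + d]
            mism = (a != b) | is_n[lo:hi] | t_is_n[lo + d : hi + d]
            for (ws, we, mm) in _maximal_windows(mism, k, params.min_len):
                i0, i1 = lo + ws, lo + we  # copy1 in s
                q0, q1 = lo + d + ws, lo + d + we  # in t coords
                c2 = (n - q1, n - q0)  # back to s coords
                add(type_, (i0, i1), c2, mm)

    if "F" in params.types:
        scan_parallel("F", s, is_n)
    if "C" in params.types:
        scan_parallel("C", comp_arr(s), is_n)
    if "R" in params.types:
        scan_anti("R", s[::-1], is_n[::-1])
    if "P" in params.types:
        scan_anti("P", comp_arr(s)[::-1], is_n[::-1])
    return sorted(hits, key=lambda h: (h.type, h.copy1, h.copy2))


def is_ir_mirror_pair(hit: RepeatHit, partition: RegionPartition) -> bool:
    """True for P hits that are the genome's own IRa/IRb duplication.

    The annotated IR pair (and any sub-pair lying at mirrored positions
    inside it) is a trivial consequence of the quadripartite structure and
    is excluded from summary counts by default.
    """
    if hit.type != "P":
        return False
    (a0, a1), (b0, b1) = hit.copy1, hit.copy2
    ira, irb = partition.ira, partition.irb
    if min(a1, ira[1]) - max(a0, ira[0]) <= 0 or min(b1, irb[1]) - max(b0, irb[0]) <= 0:
        return False
    # mirror alignment: copy1's offset into IRa equals copy2's offset from
    # the IRb end (the budget may let the pair extend slightly past the IR)
    return (a0 - ira[0]) == (irb[1] - b1) and (ira[1] - a1) == (b0 - irb[0])


def collapse_loci(
    hits: list[RepeatHit],
    partition: RegionPartition | None = None,
) -> list[RepeatLocus]:
    """Group hits into loci by (type, length, region pair of the copies)."""
    groups: dict[tuple, RepeatLocus] = {}
    for h in hits:
        if partition is not None:
            r1 = partition.region_of(*h.copy1)
            r2 = partition.region_of(*h.copy2)
        else:
            r1 = r2 = "NA"
        regions = tuple(sorted((r1, r2)))
        key = (h.type, h.length, regions)
        if key not in groups:
            groups[key] = RepeatLocus(h.type, h.length, regions)
        groups[key].members.append(h)
    return sorted(groups.values(), key=lambda l: (l.type, l.length, l.regions))


def repeat_histogram(items: list[RepeatHit] | list[RepeatLocus]) -> ReportTable:
    """Counts by length class (30-39, 40-49, 50-59, >=60) and by type."""
    def bin_label(lo, hi):
        return f"{lo}-{hi}" if hi else f">={lo}"

    header = ["class", *[bin_label(*b) for b in LENGTH_BINS], "total"]
    rows = []
    for t in REPEAT_TYPES:
        of_type = [x for x in items if x.type == t]
        cells = []
        for lo, hi in LENGTH_BINS:
            cells.append(
                sum(1 for x in of_type if x.length >= lo and (hi is None or x.length <= hi))
            )
        rows.append([t, *cells, len(of_type)])
    totals = ["all", *[sum(r[i] for r in rows) for i in range(1, len(header))]]
    rows.append(totals)
    return ReportTable("repeat_histogram", header, rows)
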