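"""Perfect microsatellite (SSR) detection, context calls, and cross-species loci.

The scanner reports every maximal perfect tandem tract whose minimal motif
period is 1-6 bp and whose complete-unit count reaches the per-period
threshold (MISA-style defaults: 10/5/4/3/3/3 for periods 1-6). Tracts are
anchored at the leftmost base of the maximal repetitive run and only whole
motif copies are counted, so tract_length == period * units always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._seq import encode
from .core_io import AlignmentMatrix, GeneFeature, ReportTable, SeqRecord
from .quadripartite import RegionPartition

DEFAULT_MIN_UNITS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRParams:
    """Per-period minimum unit counts for a perfect-SSR scan."""

    min_units: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_UNITS))

    def __post_init__(self) -> None:
        for p, u in self.min_units.items():
            if not (1 <= p <= 6):
                raise ValueError(f"SSR period {p} outside 1-6")
            if u < 2:
                raise ValueError(f"SSR threshold {u} for period {p} below 2")


@dataclass
class SSRHit:
    """One perfect SSR tract on one genome (0-based half-open interval)."""

    motif: str
    period: int
    units: int
    start: int
    end: int
    region: Optional[str] = None
    context: Optional[str] = None  # IGS | intron | CDS
    gene: Optional[str] = None

    @property
    def tract_length(self) -> int:
        return self.end - self.start


@dataclass
class SSRLocus:
    """An alignment-anchored SSR locus with per-species tract descriptors."""

    columns: tuple[int, int]
    descriptors: dict[str, Optional[tuple[str, int]]]  # id -> (motif, units) | None

    @property
    def polymorphic(self) -> bool:
        return len(set(self.descriptors.values())) >= 2


def _minimal_period(motif: str) -> int:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return d
    return p


def find_ssrs(record: SeqRecord, params: SSRParams | None = None) -> list[SSRHit]:
    """All maximal perfect SSRs of minimal period 1-6 meeting the thresholds.

    For each period p the positions where s[i] == s[i+p] are scanned for
    maximal runs; a run of r such positions is a repetitive tract of r+p
    bases. The tract is reported at its minimal period only, anchored at
    the run start, with units = floor((r+p)/p).
    """
    params = params or SSRParams()
    if "-" in record.seq:
        raise ValueError(f"record {record.id!r}: gap characters in SSR scan input")
    s = record.seq
    arr = encode(s)
    n = len(s)
    hits: list[SSRHit] = []
    for p in sorted(params.min_units):
        if n <= p:
            continue
        m = arr[:-p] == arr[p:]
        # N never forms part of an SSR tract
        valid = arr[:-p] != ord("N")
        m &= valid & (arr[p:] != ord("N"))
        # maximal runs of True in m
        padded = np.concatenate(([False], m, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for rs, re_ in zip(starts.tolist(), ends.tolist()):
            run = re_ - rs  # matching positions; tract length = run + p
            units = (run + p) // p
            if units < params.min_units[p]:
                continue
            motif = s[rs : rs + p]
            if _minimal_period(motif) != p:
                continue
            hits.append(SSRHit(motif, p, units, rs, rs + p * units))
    hits.sort(key=lambda h: (h.start, h.period))
    return hits


def _intron_intervals(feat: GeneFeature) -> list[tuple[int, int]]:
    ivs = sorted((s, e) for s, e, _ in feat.parts)
    return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ivs, ivs[1:]) if a_end < b_start]


def contextualize_ssrs(
    hits: list[SSRHit],
    features: list[GeneFeature],
    partition: RegionPartition,
) -> list[SSRHit]:
    """Fill region and genomic-context fields of each hit.

    Region is by interval containment in the partition (boundary-crossing
    tracts are 'junction-spanning'). Context: CDS if >=1 bp overlaps a CDS
    exon, else intron if inside an annotated gene between exons, else IGS
    (tRNA/rRNA exon bodies count as IGS). IGS hits are named by their
    flanking genes.
    """
    n = partition.genome_length
    out = []
    for h in hits:
        region = partition.region_of(h.start, h.end)
        context, gene = None, None
        for f in features:
            if f.kind != "CDS":
                continue
            for (s, e, _) in f.parts:
                for off in (-n, 0, n):
                    if max(h.start, s + off) < min(h.end, e + off):
                        context, gene = "CDS", f.name
                        break
                if context:
                    break
            if context:
                break
        if context is None:
            for f in features:
                for (s, e) in _intron_intervals(f):
                    if s <= h.start and h.end <= e:
                        context, gene = "intron", f.name
                        break
                if context:
                    break
        if context is None:
            context = "IGS"
            left, lbest, right, rbest = None, n, None, n
            for f in features:
                fs, fe = f.span
                dl = (h.start - fe % n) % n
                dr = (fs % n - h.end) % n
                if dl < lbest:
                    lbest, left = dl, f.name
                if dr < rbest:
                    rbest, right = dr, f.name
            if left and right:
                gene = f"{left}-{right}"
        out.append(replace(h, region=region, context=context, gene=gene))
    return out


def _ungapped_to_columns(row: str) -> np.ndarray:
    """Map ungapped sequence positions to alignment column indices."""
    arr = encode(row)
    return np.flatnonzero(arr != ord("-"))


def ssr_loci(
    alignment: AlignmentMatrix,
    per_species_hits: dict[str, list[SSRHit]],
) -> list[SSRLocus]:
    """Merge per-species SSR hits into alignment-anchored loci.

    Each hit is projected through its row's ungapped-to-column map; hits
    whose column intervals overlap are merged single-linkage into one
    locus. Species without an overlapping hit are recorded as absent.
    """
    unknown = set(per_species_hits) - set(alignment.ids)
    if unknown:
        raise KeyError(f"species not in alignment: {sorted(unknown)}")
    projected: list[tuple[int, int, str, SSRHit]] = []
    for sp, hits in per_species_hits.items():
        if not hits:
            continue
        colmap = _ungapped_to_columns(alignment.row(sp))
        for h in hits:
            if h.end > len(colmap):
                raise ValueError(f"hit beyond ungapped length of {sp!r}")
            projected.append((int(colmap[h.start]), int(colmap[h.end - 1]) + 1, sp, h))
    projected.sort(key=lambda t: (t[0], t[1]))
    loci: list[SSRLocus] = []
    cluster: list[tuple[int, int, str, SSRHit]] = []

    def flush() -> None:
        if not cluster:
            return
        lo = min(c[0] for c in cluster)
        hi = max(c[1] for c in cluster)
        desc: dict[str, Optional[tuple[str, int]]] = {sp: None for sp in alignment.ids}
        for _, _, sp, h in cluster:
            desc[sp] = (h.motif, h.units)
        loci.append(SSRLocus((lo, hi), desc))

    cur_end = -1
    for item in projected:
        if cluster and item[0] >= cur_end:
            flush()
            cluster = []
        cluster.append(item)
        cur_end = max(cur_end, item[1])
    flush()
    return loci


def ssr_summary(
    hits_by_genome: dict[str, list[SSRHit]],
    loci: list[SSRLocus] | None = None,
) -> ReportTable:
    """Per-genome SSR counts by period class, context, and region, with totals."""
    header = [
        "genome", "total",
        "mono", "di", "tri", "tetra", "penta", "hexa",
        "IGS", "intron", "CDS",
        "LSC", "IR", "SSC", "junction",
    ]
    rows = []
    for genome in sorted(hits_by_genome):
        hits = hits_by_genome[genome]
        by_p = [sum(1 for h in hits if h.period == p) for p in range(1, 7)]
        by_c = [sum(1 for h in hits if h.context == c) for c in ("IGS", "intron", "CDS")]
        n_ir = sum(1 for h in hits if h.region in ("IRa", "IRb"))
        by_r = [
            sum(1 for h in hits if h.region == "LSC"),
            n_ir,
            sum(1 for h in hits if h.region == "SSC"),
            sum(1 for h in hits if h.region == "junction-spanning"),
        ]
        rows.append([genome, len(hits), *by_p, *by_c, *by_r])
    totals = ["total", *[sum(r[i] for r in rows) for i in range(1, len(header))]]
    rows.append(totals)
    table = ReportTable("ssr_summary", header, rows)
    if loci is not None:
        n_poly = sum(1 for l in loci if l.polymorphic)
        pct = 100.0 * n_poly / len(loci) if loci else 0.0
        table.rows.append(
            ["aligned_loci", len(loci), *[""] * 6, "", "", "", "polymorphic", n_poly, "pct", pct]
        )
    return table
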