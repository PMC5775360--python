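"""Quadripartite structure detection and IR-junction analysis.

A plastome is modelled as a circular sequence carrying two inverted-repeat
copies (IRa, IRb; one the reverse complement of the other) separating a
large and a small single-copy region (LSC, SSC). The IR extent is taken as
the longest pair of disjoint maximal *exact* inverted repeats, matching how
published IR lengths are conventionally reported. Detection canonicalizes
the genome: rotated so LSC starts at base 1 and strand-flipped to a stable
orientation, giving region order LSC, IRa, SSC, IRb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from ._seq import revcomp
from .core_io import GeneFeature, SeqRecord

log = logging.getLogger(__name__)

JUNCTIONS = ("LSC/IRa", "IRa/SSC", "SSC/IRb", "IRb/LSC")


class NoIRFoundError(ValueError):
    pass


class AmbiguousIRError(ValueError):
    pass


@dataclass(frozen=True)
class RegionPartition:
    """LSC/IRa/SSC/IRb intervals on the canonicalized linear coordinates.

    The four intervals tile [0, genome_length) in order; len(lsc) >= len(ssc)
    and the IRa sequence equals the reverse complement of the IRb sequence.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    def region_of(self, start: int, end: int) -> str:
        """Region containing [start, end), or 'junction-spanning'."""
        for name, (rs, re_) in self.regions.items():
            if rs <= start and end <= re_:
                return name
        return "junction-spanning"

    def junction_positions(self) -> dict[str, int]:
        """Boundary coordinates; IRb/LSC is the circular origin (= length)."""
        return {
            "LSC/IRa": self.lsc[1],
            "IRa/SSC": self.ira[1],
            "SSC/IRb": self.ssc[1],
            "IRb/LSC": self.genome_length,
        }

    def validate(self, seq: str | None = None) -> "RegionPartition":
        n = self.genome_length
        ivs = [self.lsc, self.ira, self.ssc, self.irb]
        if ivs[0][0] != 0 or ivs[-1][1] != n:
            raise ValueError("partition must start at 0 and end at genome length")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if b != c or a >= b:
                raise ValueError("partition intervals must tile the genome in order")
        if self.lsc[1] - self.lsc[0] < self.ssc[1] - self.ssc[0]:
            raise ValueError("LSC must be at least as long as SSC")
        if (self.ira[1] - self.ira[0]) != (self.irb[1] - self.irb[0]):
            raise ValueError("IR copies must have equal length")
        if seq is not None:
            ira = seq[self.ira[0] : self.ira[1]]
            irb = seq[self.irb[0] : self.irb[1]]
            if ira != revcomp(irb):
                raise ValueError("IRa is not the reverse complement of IRb")
        return self


@dataclass
class JunctionRecord:
    """One gene (or intergenic gap) at one of the four region boundaries.

    bp_left/bp_right split the gene span across the junction. For the
    "intergenic" record of a gene-free junction they hold the distances to
    the flanking genes named in flank_left/flank_right.
    """

    junction: str
    gene: str
    bp_left: int
    bp_right: int
    overlap_partner: Optional[tuple[str, int]] = None
    flank_left: Optional[str] = None
    flank_right: Optional[str] = None


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = {}
    for i in range(len(seq)):
        d.setdefault(seq[i : i + k] if i + k <= len(seq) else seq[i:] + seq[: i + k - len(seq)], []).append(i)
    return d


def _maximal_inverted_pairs(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact inverted-repeat pairs >= min_len on the circle.

    Returns (a, b, L) with copy1 = [a, a+L), copy2 = [b, b+L) taken modulo n
    and seq[a+t] == comp(seq[b+L-1-t]). Copies are disjoint on the circle.
    """
    n = len(seq)
    k = min(min_len, 24)
    if k < 4:
        raise ValueError("min_ir_len too small")
    comp = dict(zip("ACGTN", "TGCA?"))  # N never matches during extension
    trip = seq * 3  # index i+n is position i; room to extend both ways
    kmers = _seed_positions(seq, k)
    found: dict[tuple[int, int, int], None] = {}
    seen_seeds: set[tuple[int, int]] = set()
    max_len = n // 2
    for j in range(n):
        rc_kmer = revcomp(trip[n + j : n + j + k])
        if "N" in rc_kmer:
            continue
        for i in kmers.get(rc_kmer, ()):
            if (min(i, j), max(i, j)) in seen_seeds:
                continue
            # extend maximally: copy1 at a (in trip coords, base n), copy2 at b
            a, b, L = n + i, n + j, k
            while L < max_len and trip[a - 1] == comp[trip[b + L]]:
                a -= 1
                L += 1
            while L < max_len and trip[a + L] == comp[trip[b - 1]]:
                b -= 1
                L += 1
            am, bm = a % n, b % n
            c1, c2 = min(am, bm), max(am, bm)
            found[(c1, c2, L)] = None
            # a seed at copy1 offset t pairs with copy2 offset L-k-t
            for t in range(L - k + 1):
                p1, p2 = (a + t) % n, (b + L - k - t) % n
                seen_seeds.add((min(p1, p2), max(p1, p2)))
    out = []
    for (a, b, L) in found:
        if L < min_len or a == b:
            continue
        # disjoint on the circle: intervals [a,a+L), [b,b+L) mod n
        if b < a + L and a < b + L:  # linear overlap
            continue
        if a + n < b + L:  # wrap overlap of copy2 into copy1
            continue
        out.append((a, b, L))
    return sorted(out)


def _rotate(seq: str, offset: int) -> str:
    return seq[offset:] + seq[:offset]


def at_content(record: SeqRecord) -> float:
    """(A+T) / (non-N bases), as a fraction in [0, 1]."""
    s = record.seq
    denom = len(s) - s.count("N") - s.count("-")
    if denom == 0:
        raise ValueError(f"record {record.id!r}: AT content undefined (all N)")
    return (s.count("A") + s.count("T")) / denom


def detect_quadripartite(
    record: SeqRecord,
    min_ir_len: int = 1000,
    features: list[GeneFeature] | None = None,
) -> tuple[SeqRecord, RegionPartition, list[GeneFeature] | None]:
    """Detect the LSC/IRa/SSC/IRb partition and canonicalize the genome.

    Returns the rotated/strand-flipped record, the partition on its
    coordinates, and (when supplied) the features remapped to that frame.
    Orientation: LSC is the longer single-copy region; the strand is chosen
    so the majority of LSC CDS bases are forward (with annotations), else
    the lexicographically smaller LSC sequence.
    """
    if not record.circular:
        raise ValueError("quadripartite detection requires a circular record")
    n = len(record.seq)
    if n < 10_000:
        log.warning("genome %s is only %d bp; quadripartite structure may be spurious", record.id, n)
    pairs = _maximal_inverted_pairs(record.seq, min_ir_len)
    if not pairs:
        raise NoIRFoundError(f"{record.id}: no inverted repeat >= {min_ir_len} bp found")
    best_len = max(L for _, _, L in pairs)
    cands = [p for p in pairs if p[2] == best_len]
    if len(cands) > 1:
        # prefer the pair whose single-copy gaps are most balanced, then lowest start
        def gap_lengths(p):
            a, b, L = p
            g1 = (b - (a + L)) % n
            g2 = (a - (b + L)) % n
            return abs(g1 - g2)

        cands.sort(key=lambda p: (gap_lengths(p), p[0]))
        if gap_lengths(cands[0]) == gap_lengths(cands[1]) and cands[0][0] == cands[1][0]:
            raise AmbiguousIRError(f"{record.id}: tied maximal IR candidates")
    a, b, L = cands[0]
    gap_ab = (b - (a + L)) % n  # gap after copyA (at a) before copyB
    gap_ba = (a - (b + L)) % n
    # LSC = longer gap; canonical layout LSC, IRa, SSC, IRb
    if gap_ab >= gap_ba:
        lsc_len, ssc_len = gap_ab, gap_ba
        lsc_start = (a + L) % n  # LSC follows copyA; IRa is copyB
    else:
        lsc_len, ssc_len = gap_ba, gap_ab
        lsc_start = (b + L) % n
    part = RegionPartition(
        lsc=(0, lsc_len),
        ira=(lsc_len, lsc_len + L),
        ssc=(lsc_len + L, lsc_len + L + ssc_len),
        irb=(lsc_len + L + ssc_len, n),
        genome_length=n,
    )
    fwd_seq = _rotate(record.seq, lsc_start)
    # flipped orientation: revcomp(fwd) = IRa | rc(SSC) | IRb | rc(LSC);
    # rotating by 2L+ssc puts rc(LSC) first with IRa/IRb fixed in place,
    # so the partition intervals are identical in both frames.
    rev_full = revcomp(fwd_seq)
    flip_seq = _rotate(rev_full, 2 * L + ssc_len)

    def remap_pos_fwd(p: int) -> int:
        return (p - lsc_start) % n

    def remap_pos_flip(p: int) -> int:
        # fwd-frame q maps to (lsc_len - 1 - q) mod n in the flipped frame
        q = remap_pos_fwd(p)
        return (lsc_len - 1 - q) % n

    use_flip = _choose_flip(fwd_seq, flip_seq, part, features, remap_pos_fwd, remap_pos_flip)
    canon_seq = flip_seq if use_flip else fwd_seq
    canon = SeqRecord(record.id, canon_seq, circular=True)
    part.validate(canon_seq)
    out_features = None
    if features is not None:
        out_features = [
            _remap_feature(f, remap_pos_flip if use_flip else remap_pos_fwd, n, use_flip)
            for f in features
        ]
    return canon, part, out_features


def _choose_flip(fwd_seq, flip_seq, part, features, remap_fwd, remap_flip) -> bool:
    if features:
        def lsc_cds_fwd_bases(remap, flipped):
            total = fwd = 0
            for f in features:
                if f.kind != "CDS":
                    continue
                for (s, e, strand) in f.parts:
                    ns = remap(s)
                    if not (part.lsc[0] <= ns < part.lsc[1]):
                        continue
                    eff = strand if not flipped else ("-" if strand == "+" else "+")
                    total += e - s
                    if eff == "+":
                        fwd += e - s
            return fwd, total

        f_fwd, t1 = lsc_cds_fwd_bases(remap_fwd, False)
        f_flip, t2 = lsc_cds_fwd_bases(remap_flip, True)
        if t1 or t2:
            return f_flip > f_fwd
    return flip_seq[part.lsc[0] : part.lsc[1]] < fwd_seq[part.lsc[0] : part.lsc[1]]


def _remap_feature(feat: GeneFeature, remap, n: int, flipped: bool) -> GeneFeature:
    parts = []
    for (s, e, strand) in feat.parts:
        if flipped:
            ns, ne = remap(e - 1), remap(s) + 1
            strand = "-" if strand == "+" else "+"
        else:
            ns, ne = remap(s), remap(e - 1) + 1
        if ne <= ns:  # crosses the origin: unwrap past n
            ne += n
        parts.append((ns, ne, strand))
    parts = sorted(parts)
    if parts[0][2] == "-":
        parts = parts[::-1]
    return GeneFeature(feat.name, feat.kind, parts)


def _gene_span_mod(feat: GeneFeature, n: int) -> tuple[int, int]:
    s, e = feat.span
    return s % n, s % n + (e - s)


def junction_table(
    partition: RegionPartition, features: list[GeneFeature]
) -> list[JunctionRecord]:
    """Per-junction records of the genes crossing each region boundary.

    Genes overlapping one another at a junction carry the partner and the
    overlap length; a junction crossed by no gene yields one 'intergenic'
    record whose bp fields are the distances to the named flanking genes.
    """
    n = partition.genome_length
    records: list[JunctionRecord] = []
    spans = [(f, *_gene_span_mod(f, n)) for f in features]
    for junction, pos in partition.junction_positions().items():
        # a gene crosses boundary pos if span contains pos strictly inside,
        # testing both the unwrapped and +n images for origin-crossing genes
        crossing = []
        for f, s, e in spans:
            for off in (0, n):
                if s < pos + off < e:
                    crossing.append((f, s - off, e - off))
                    break
        if crossing:
            for f, s, e in sorted(crossing, key=lambda t: t[1]):
                partner = None
                best = 0
                for g, gs, ge in spans:
                    if g is f:
                        continue
                    for off in (-n, 0, n):
                        ov = min(e, ge + off) - max(s, gs + off)
                        if ov > best:
                            best = ov
                            partner = (g.name, ov)
                records.append(
                    JunctionRecord(junction, f.name, pos - s, e - pos, overlap_partner=partner)
                )
        else:
            left_gene, left_gap = None, n
            right_gene, right_gap = None, n
            for f, s, e in spans:
                dist_l = (pos - e) % n
                dist_r = (s - pos) % n
                if dist_l < left_gap:
                    left_gap, left_gene = dist_l, f.name
                if dist_r < right_gap:
                    right_gap, right_gene = dist_r, f.name
            records.append(
                JunctionRecord(
                    junction,
                    "intergenic",
                    left_gap if left_gene else 0,
                    right_gap if right_gene else 0,
                    flank_left=left_gene,
                    flank_right=right_gene,
                )
            )
    return records
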