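"""Seeded synthetic-plastome generator with recorded ground truth.

Builds toy circular quadripartite genomes (LSC + IRa + SSC + IRb with
IRa the reverse complement of IRb) carrying planted, recorded elements
for every pipeline stage: junction-spanning genes with known bp splits
and overlaps, perfect SSRs of periods 1-5, large repeats of all four
types at chosen Hamming distances, and designated high-substitution
(hotspot) intervals. Species sequences are then evolved along a known
tree by a substitution-only Jukes-Cantor process, so the true alignment
is the identity mapping onto ancestor coordinates.

Mutations applied to IRa are mirrored into IRb (plastome IR copies evolve
in concert), and the IR substitution rate is damped by default to mimic
the low IR diversity of real plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from ._seq import decode, encode, revcomp, revcomp_arr
from .core_io import AlignmentMatrix, GeneFeature, SeqRecord
from .quadripartite import RegionPartition

_BASES = "ACGT"
_BASE_CODES = encode(_BASES)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    units: int
    start: int  # absolute ancestor coordinate
    # per-species unit counts (<= units); other species keep the full tract
    species_units: dict[str, int] = field(default_factory=dict)

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def end(self) -> int:
        return self.start + self.period * self.units


@dataclass(frozen=True)
class PlantedRepeat:
    type: str  # F, R, C, P
    length: int
    mismatches: int
    start1: int
    start2: int


@dataclass(frozen=True)
class PlantedGene:
    name: str
    kind: str
    parts: tuple[tuple[int, int, str], ...]


@dataclass(frozen=True)
class JunctionTruth:
    junction: str
    gene: str
    bp_left: int
    bp_right: int
    overlap_partner: Optional[tuple[str, int]] = None


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study; the defaults are the study."""

    seed: int = 0
    lsc_len: int = 11_000
    ir_len: int = 2_500
    ssc_len: int = 4_000
    at_fraction: float = 0.63
    genes: tuple[PlantedGene, ...] = ()
    ssrs: tuple[PlantedSSR, ...] = ()
    repeats: tuple[PlantedRepeat, ...] = ()
    hotspots: tuple[tuple[int, int], ...] = ()
    hotspot_multiplier: float = 10.0
    ir_damp: float = 0.2
    tree_newick: str = (
        "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01,"
        "((E:0.01,F:0.01):0.01,(G:0.01,H:0.01):0.01):0.01);"
    )
    junction_truth: tuple[JunctionTruth, ...] = ()

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def partition(self) -> RegionPartition:
        l, i, s = self.lsc_len, self.ir_len, self.ssc_len
        return RegionPartition(
            lsc=(0, l), ira=(l, l + i), ssc=(l + i, l + i + s),
            irb=(l + i + s, l + 2 * i + s), genome_length=self.genome_length,
        )


@dataclass
class TruthBundle:
    """Everything the generator knows about one simulated dataset."""

    config: SimConfig
    ancestor: SeqRecord
    features: list[GeneFeature]
    partition: RegionPartition
    species: dict[str, SeqRecord] | None = None
    alignment: AlignmentMatrix | None = None

    @property
    def planted_ssrs(self) -> tuple[PlantedSSR, ...]:
        return self.config.ssrs

    @property
    def planted_repeats(self) -> tuple[PlantedRepeat, ...]:
        return self.config.repeats

    @property
    def hotspot_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.config.hotspots


def default_config(seed: int = 0) -> SimConfig:
    """The standard 8-taxon, 20 kb synthetic study.

    Geometry: LSC 11 kb, IRs 2.5 kb, SSC 4 kb. Junction genes mimic the
    plastome convention: rps19 crossing LSC/IRa (180/99 bp), ndhF crossing
    IRa/SSC (8/2225 bp) overlapping a ycf1 fragment by 25 bp, the fragment
    itself reaching 17 bp into the SSC, and ycf1 crossing SSC/IRb
    (1000/406 bp). Three 800 bp hotspot intervals (two LSC intergenic
    spacers, one inside ycf1) run at 10x the background rate of 0.01
    substitutions/site per branch.
    """
    genes = (
        PlantedGene("trnK", "tRNA", ((300, 500, "+"),)),
        PlantedGene("rps16", "CDS", ((1500, 1700, "+"), (1800, 1900, "+"))),
        PlantedGene("psbM", "CDS", ((3000, 3200, "+"),)),
        PlantedGene("trnD", "tRNA", ((4200, 4280, "+"),)),
        PlantedGene("ycf4", "CDS", ((5200, 5800, "+"),)),
        PlantedGene("cemA", "CDS", ((6500, 7100, "+"),)),
        PlantedGene("petA", "CDS", ((8100, 8600, "+"),)),
        PlantedGene("psbJ", "CDS", ((10200, 10400, "+"),)),
        PlantedGene("rps19", "CDS", ((10820, 11099, "+"),)),
        PlantedGene("ycf1_psi", "CDS", ((13090, 13517, "+"),)),
        PlantedGene("ndhF", "CDS", ((13492, 15725, "-"),)),
        PlantedGene("rpl32", "CDS", ((15800, 15980, "+"),)),
        PlantedGene("trnL", "tRNA", ((16050, 16130, "+"),)),
        PlantedGene("ycf1", "CDS", ((16500, 17906, "-"),)),
    )
    ssrs = (
        PlantedSSR("A", 12, 2200, species_units={"B": 10, "E": 11}),
        PlantedSSR("AT", 7, 2400, species_units={"C": 5}),
        PlantedSSR("TTC", 5, 4500),
        PlantedSSR("AATG", 4, 1720),            # rps16 intron
        PlantedSSR("AACCT", 3, 5400),           # ycf4 CDS
    )
    repeats = (
        PlantedRepeat("F", 40, 0, 7250, 9550),
        PlantedRepeat("P", 45, 2, 7350, 9650),
        PlantedRepeat("R", 35, 0, 7450, 9750),
        PlantedRepeat("C", 32, 1, 7550, 9850),
    )
    hotspots = ((600, 1400), (3300, 4100), (16550, 17350))
    junction_truth = (
        JunctionTruth("LSC/IRa", "rps19", 180, 99),
        JunctionTruth("IRa/SSC", "ycf1_psi", 410, 17, ("ndhF", 25)),
        JunctionTruth("IRa/SSC", "ndhF", 8, 2225, ("ycf1_psi", 25)),
        JunctionTruth("SSC/IRb", "ycf1", 1000, 406),
    )
    return SimConfig(
        seed=seed,
        genes=genes,
        ssrs=ssrs,
        repeats=repeats,
        hotspots=hotspots,
        junction_truth=junction_truth,
    )


def toy_config(seed: int, lsc_len: int = 2000, ir_len: int = 600, ssc_len: int = 800) -> SimConfig:
    """A bare quadripartite genome with no planted elements (partition tests)."""
    return SimConfig(seed=seed, lsc_len=lsc_len, ir_len=ir_len, ssc_len=ssc_len)


def small_config(seed: int = 0) -> SimConfig:
    """A 5.6 kb miniature of the default study for fast end-to-end runs.

    Same structure as :func:`default_config` — junction genes with known
    splits and a 25 bp overlap, planted SSRs of periods 1-5, one planted
    repeat of each type, three hotspot intervals — at roughly a quarter of
    the scale.
    """
    genes = (
        PlantedGene("trnK", "tRNA", ((150, 250, "+"),)),
        PlantedGene("rps16", "CDS", ((500, 600, "+"), (650, 700, "+"))),
        PlantedGene("psbM", "CDS", ((900, 1000, "+"),)),
        PlantedGene("trnD", "tRNA", ((1300, 1340, "+"),)),
        PlantedGene("ycf4", "CDS", ((1600, 1800, "+"),)),
        PlantedGene("cemA", "CDS", ((1900, 2100, "+"),)),
        PlantedGene("rps19", "CDS", ((2920, 3060, "+"),)),
        PlantedGene("ycf1_psi", "CDS", ((3560, 3717, "+"),)),
        PlantedGene("ndhF", "CDS", ((3692, 4200, "-"),)),
        PlantedGene("rpl32", "CDS", ((4300, 4380, "+"),)),
        PlantedGene("trnL", "tRNA", ((4420, 4460, "+"),)),
        PlantedGene("ycf1", "CDS", ((4650, 5100, "-"),)),
    )
    ssrs = (
        PlantedSSR("A", 12, 720, species_units={"B": 10, "E": 11}),
        PlantedSSR("AT", 7, 740, species_units={"C": 5}),
        PlantedSSR("TTC", 5, 1400),
        PlantedSSR("AATG", 4, 610),     # rps16 intron
        PlantedSSR("AACCT", 3, 1650),   # ycf4 CDS
    )
    repeats = (
        PlantedRepeat("F", 40, 0, 2200, 2500),
        PlantedRepeat("P", 45, 2, 2250, 2560),
        PlantedRepeat("R", 35, 0, 2300, 2620),
        PlantedRepeat("C", 32, 1, 2350, 2680),
    )
    hotspots = ((1050, 1300), (1420, 1580), (4650, 4900))
    junction_truth = (
        JunctionTruth("LSC/IRa", "rps19", 80, 60),
        JunctionTruth("IRa/SSC", "ycf1_psi", 140, 17, ("ndhF", 25)),
        JunctionTruth("IRa/SSC", "ndhF", 8, 500, ("ycf1_psi", 25)),
        JunctionTruth("SSC/IRb", "ycf1", 250, 200),
    )
    return SimConfig(
        seed=seed,
        lsc_len=3000,
        ir_len=700,
        ssc_len=1200,
        genes=genes,
        ssrs=ssrs,
        repeats=repeats,
        hotspots=hotspots,
        junction_truth=junction_truth,
    )


def _random_dna(rng: np.random.Generator, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return rng.choice(_BASE_CODES, size=n, p=[p_at, p_gc, p_gc, p_at])


def _pick_base(rng: np.random.Generator, exclude: set[str]) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[rng.integers(len(choices))]


def _comp(c: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[c]


def simulate_plastome(config: SimConfig) -> TruthBundle:
    """Build the ancestor genome with all planted elements at recorded spots."""
    rng = np.random.default_rng(config.seed)
    part = config.partition
    n = config.genome_length
    lsc = _random_dna(rng, config.lsc_len, config.at_fraction)
    ira = _random_dna(rng, config.ir_len, config.at_fraction)
    ssc = _random_dna(rng, config.ssc_len, config.at_fraction)
    # orientation guard: LSC begins and ends with 'A', so LSC is always
    # lexicographically smaller than its reverse complement (starts with T)
    lsc[0] = lsc[-1] = ord("A")
    # IR non-extension guards: neither IR flank may extend the exact pair
    if ssc[0] == revcomp_arr(ssc[-1:])[0]:
        ssc[0] = encode(_pick_base(rng, {_comp(chr(ssc[-1])), "N"}))[0]
    seq = np.concatenate([lsc, ira, ssc, revcomp_arr(ira)])
    _check_planted_fit(config)
    s = list(decode(seq))
    for ssr in config.ssrs:
        _plant_ssr(s, ssr, rng)
    for rep in config.repeats:
        _plant_repeat(s, rep, rng)
    # re-mirror IRb in case a planted element touched IRa
    ira_s = "".join(s[part.ira[0] : part.ira[1]])
    s[part.irb[0] : part.irb[1]] = list(revcomp(ira_s))
    ancestor = SeqRecord("ancestor", "".join(s), circular=True)
    features = [GeneFeature(g.name, g.kind, list(g.parts)) for g in config.genes]
    bundle = TruthBundle(config, ancestor, features, part)
    part.validate(ancestor.seq)
    return bundle


def _check_planted_fit(config: SimConfig) -> None:
    n = config.genome_length
    intervals = []
    for ssr in config.ssrs:
        intervals.append((ssr.start - 1, ssr.end + 1, f"SSR@{ssr.start}"))
    for rep in config.repeats:
        for st in (rep.start1, rep.start2):
            intervals.append((st - 1, st + rep.length + 1, f"repeat@{st}"))
    for (a, b, label) in intervals:
        if a < 0 or b > n:
            raise ConfigError(f"planted element {label} outside genome")
    intervals.sort()
    for (a1, b1, l1), (a2, b2, l2) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise ConfigError(f"planted elements overlap: {l1} and {l2}")


def _plant_ssr(s: list[str], ssr: PlantedSSR, rng: np.random.Generator) -> None:
    tract = ssr.motif * ssr.units
    s[ssr.start : ssr.end] = list(tract)
    _guard_ssr(s, ssr)


def _guard_ssr(s: list[str], ssr: PlantedSSR) -> None:
    # stop run extension: left neighbour must differ from the motif's last
    # base, right neighbour from its first
    if ssr.start > 0 and s[ssr.start - 1] == ssr.motif[-1]:
        s[ssr.start - 1] = "G" if ssr.motif[-1] != "G" else "C"
    if ssr.end < len(s) and s[ssr.end] == ssr.motif[0]:
        s[ssr.end] = "G" if ssr.motif[0] != "G" else "C"


def _plant_repeat(s: list[str], rep: PlantedRepeat, rng: np.random.Generator) -> None:
    L = rep.length
    a, b = rep.start1, rep.start2
    copy1 = [_BASES[rng.integers(4)] for _ in range(L)]
    s[a : a + L] = copy1
    if rep.type == "F":
        copy2 = list(copy1)
    elif rep.type == "R":
        copy2 = copy1[::-1]
    elif rep.type == "C":
        copy2 = [_comp(c) for c in copy1]
    elif rep.type == "P":
        copy2 = [_comp(c) for c in copy1[::-1]]
    else:
        raise ConfigError(f"unknown repeat type {rep.type!r}")
    if rep.mismatches:
        pos = rng.choice(np.arange(1, L - 1), size=rep.mismatches, replace=False)
        for p in pos:
            copy2[p] = _pick_base(rng, {copy2[p]})
    s[b : b + L] = copy2
    # flank guards so the pair is maximal exactly at the planted budget
    if rep.type in ("F", "C"):
        pairs = [(a - 1, b - 1), (a + L, b + L)]
    else:  # R, P: anti-parallel
        pairs = [(a - 1, b + L), (a + L, b - 1)]
    comp_like = rep.type in ("C", "P")
    for (x, y) in pairs:
        if 0 <= x < len(s) and 0 <= y < len(s):
            match = s[x] == (_comp(s[y]) if comp_like else s[y])
            if match:
                s[x] = _pick_base(rng, {s[x], _comp(s[y]) if comp_like else s[y]})


def _jc_mutate(
    seq: np.ndarray,
    t: float,
    rate_mult: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of Jukes-Cantor evolution with per-site rate multipliers.

    Per-site change probability is the exact JC transition
    0.75 * (1 - exp(-4/3 * t * mult)), so branch composition reproduces
    the closed-form expected p-distance at the summed branch lengths.
    """
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * t * rate_mult))
    out = seq.copy()
    hit = rng.random(len(seq)) < p_change
    idx = np.flatnonzero(hit)
    if len(idx):
        cur = out[idx]
        shift = rng.integers(1, 4, size=len(idx))  # uniform over the other 3 bases
        cur_pos = np.argmax(cur[:, None] == _BASE_CODES[None, :], axis=1)
        out[idx] = _BASE_CODES[(cur_pos + shift) % 4]
    return out


def evolve(bundle: TruthBundle) -> TruthBundle:
    """Evolve the ancestor along the configured tree; fill species + alignment.

    Substitution-only: the true alignment columns correspond 1:1 to
    ancestor positions. IRa mutations are mirrored into IRb each branch;
    the IR substitution rate is damped by config.ir_damp. After evolution,
    planted SSR tracts are rewritten per species to their configured unit
    counts (with run guards), so SSR locus truth is exact.
    """
    config = bundle.config
    part = bundle.partition
    n = config.genome_length
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rate_mult = np.ones(n)
    for (a, b) in config.hotspots:
        if not (
            (part.lsc[0] <= a and b <= part.lsc[1])
            or (part.ssc[0] <= a and b <= part.ssc[1])
        ):
            raise ConfigError(f"hotspot ({a}, {b}) not inside LSC or SSC")
        rate_mult[a:b] = config.hotspot_multiplier
    rate_mult[part.ira[0] : part.ira[1]] = config.ir_damp
    rate_mult[part.irb[0] : part.irb[1]] = 0.0  # mirrored, never mutated directly

    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    root_seq = encode(bundle.ancestor.seq).copy()
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    species: dict[str, SeqRecord] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        child = _jc_mutate(seqs[id(node.parent_node)], t, rate_mult, rng)
        child[part.irb[0] : part.irb[1]] = revcomp_arr(child[part.ira[0] : part.ira[1]])
        seqs[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label
            sp = list(decode(child))
            for ssr in config.ssrs:
                _rewrite_species_ssr(sp, ssr, label)
            ira_s = "".join(sp[part.ira[0] : part.ira[1]])
            sp[part.irb[0] : part.irb[1]] = list(revcomp(ira_s))
            species[label] = SeqRecord(label, "".join(sp), circular=True)
    ids = sorted(species)
    alignment = AlignmentMatrix.from_strings(ids, [species[i].seq for i in ids])
    return replace_bundle(bundle, species=species, alignment=alignment)


def _rewrite_species_ssr(s: list[str], ssr: PlantedSSR, label: str) -> None:
    units = ssr.species_units.get(label, ssr.units)
    if units > ssr.units:
        raise ConfigError(
            f"species {label!r} SSR units {units} exceed planted {ssr.units} "
            "(substitution-only evolution cannot lengthen tracts)"
        )
    p = ssr.period
    tract = ssr.motif * units
    filler_unit = "GC" if ("G" not in ssr.motif or "C" not in ssr.motif) else "AT"
    if filler_unit[0] == ssr.motif[0]:
        filler_unit = filler_unit[::-1]
    fill_len = (ssr.units - units) * p
    fill = (filler_unit * fill_len)[:fill_len]
    s[ssr.start : ssr.end] = list(tract + fill)
    _guard_ssr(s, PlantedSSR(ssr.motif, units, ssr.start))


def replace_bundle(bundle: TruthBundle, **kw) -> TruthBundle:
    return TruthBundle(
        config=bundle.config,
        ancestor=bundle.ancestor,
        features=bundle.features,
        partition=bundle.partition,
        species=kw.get("species", bundle.species),
        alignment=kw.get("alignment", bundle.alignment),
    )


def simulate(config: SimConfig) -> TruthBundle:
    """Convenience: simulate the ancestor and evolve the species in one call."""
    return evolve(simulate_plastome(config))
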