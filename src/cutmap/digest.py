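"""Bipartite-site scanning, staggered cleavage and library-prep emulation.

The modeled enzyme is a modification-dependent (type IV) restriction
endonuclease recognizing a bipartite site: two modified cytosines on opposite
strands separated by a fixed nonspecific spacer, written ``CN11/N9G`` with the
``/`` marking the top-strand nick. With the default geometry the top strand is
nicked 11 intervening bases downstream of the modified C and the bottom strand
9 intervening bases upstream of the distal G's paired C, leaving a 2-nt
3' overhang. Both half-sites must carry a cleavable class (hm5C or ghm5C);
unmodified C and m5C are refractory, and a lone modified cytosine is not cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import (
    BOTTOM,
    CLEAVABLE_CLASSES,
    TOP,
    ModClass,
    ModifiedGenome,
    derive_rng,
    reverse_complement,
)

__all__ = [
    "THREE_PRIME",
    "FIVE_PRIME",
    "RecognitionRule",
    "RecognitionSite",
    "DuplexCut",
    "EndChemistry",
    "BLUNT_END",
    "Fragment",
    "RepairedInterval",
    "ReadPair",
    "find_recognition_sites",
    "cut_positions",
    "simulate_digest",
    "end_repair",
    "emit_read_pairs",
    "write_fragments_bed",
    "write_intervals_bed",
    "read_intervals_bed",
    "write_fastq_pairs",
]

logger = logging.getLogger(__name__)

THREE_PRIME = "3'"
FIVE_PRIME = "5'"


@dataclass(frozen=True)
class RecognitionRule:
    """Geometry and modification requirements of the bipartite site.

    Parameters
    ----------
    spacing : int
        Top-strand distance ``s`` between the upstream modified C and the G
        paired with the downstream modified C. The site spans ``s + 1`` bases.
    offset_modified : int
        ``u``, intervening bases between a modified C and the nick on its own
        strand.
    offset_other : int
        ``v``, intervening bases between the nick and the distal conserved
        base on the same strand.
    required_classes : frozenset of ModClass
        Classes either half-site must carry for the site to be recognized.
    efficiency : mapping ModClass -> float
        Per-class cleavage probability; a site is cut with the minimum of its
        two half-site efficiencies (both half-sites must engage).
    enforce_bipartite_span : bool
        Keep the defining constraint ``s = u + v + 1``; disable only to
        simulate hypothetical enzymes with decoupled geometry.
    """

    spacing: int = 21
    offset_modified: int = 11
    offset_other: int = 9
    required_classes: frozenset = CLEAVABLE_CLASSES
    efficiency: tuple = ((ModClass.hm5C, 1.0), (ModClass.ghm5C, 1.0))
    enforce_bipartite_span: bool = True

    def __post_init__(self) -> None:
        if self.offset_modified < 0 or self.offset_other < 0:
            raise ValueError("offsets must be non-negative")
        if self.enforce_bipartite_span and self.spacing != (
            self.offset_modified + self.offset_other + 1
        ):
            raise ValueError(
                f"spacing {self.spacing} != u + v + 1 = "
                f"{self.offset_modified + self.offset_other + 1}"
            )
        object.__setattr__(self, "efficiency", tuple(self.efficiency))
        object.__setattr__(
            self, "required_classes", frozenset(self.required_classes)
        )
        for _, e in self.efficiency:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency {e} outside [0, 1]")

    @classmethod
    def from_offsets(cls, u: int, v: int, **kw) -> "RecognitionRule":
        return cls(spacing=u + v + 1, offset_modified=u, offset_other=v, **kw)

    @property
    def overhang(self) -> int:
        """Signed overhang ``o = u - v``: positive 3', negative 5', zero blunt."""
        return self.offset_modified - self.offset_other

    def class_efficiency(self, cls_: ModClass) -> float:
        return dict(self.efficiency).get(cls_, 0.0)

    def site_efficiency(self, site: "RecognitionSite") -> float:
        return min(self.class_efficiency(c) for c in site.classes)


@dataclass(frozen=True)
class RecognitionSite:
    """A concrete bipartite site: top-strand coordinate of the upstream
    modified C, plus the classes of the two strand-wise cytosines."""

    genome_id: str
    p: int
    classes: tuple[ModClass, ModClass]


@dataclass(frozen=True)
class DuplexCut:
    """A double-strand break: one nick boundary per strand.

    ``top_nick - bottom_nick`` equals the signed overhang of the generating
    rule.
    """

    top_nick: int
    bottom_nick: int

    @property
    def overhang(self) -> int:
        return self.top_nick - self.bottom_nick


@dataclass(frozen=True)
class EndChemistry:
    """End state of one fragment side: blunt, or an overhang with length,
    polarity and the strand that protrudes."""

    kind: str  # "blunt" | "overhang"
    length: int = 0
    polarity: str = "blunt"  # "3'" | "5'" | "blunt"
    protruding_strand: str = ""  # "top" | "bottom" | ""

    @property
    def is_blunt(self) -> bool:
        return self.kind == "blunt"


BLUNT_END = EndChemistry(kind="blunt")


@dataclass(frozen=True)
class Fragment:
    """A digestion product: the double-stranded core interval plus the end
    chemistry on each side. Genome-terminal ends are blunt."""

    genome_id: str
    start: int
    end: int
    left_end: EndChemistry = BLUNT_END
    right_end: EndChemistry = BLUNT_END

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment core [{self.start}, {self.end})")


@dataclass(frozen=True)
class RepairedInterval:
    """The blunted, mapped footprint of a fragment after end repair."""

    genome_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: str
    mate2: str


def find_recognition_sites(
    genome: ModifiedGenome, rule: RecognitionRule
) -> list[RecognitionSite]:
    """All positions carrying a complete bipartite site, sorted by coordinate.

    A site at ``p`` needs a top-strand C at ``p`` and a top-strand G at
    ``p + s`` with both strand-wise cytosines carrying a required class;
    windows running off the genome ends are never reported.
    """
    s = rule.spacing
    L = len(genome.seq)
    sites: list[RecognitionSite] = []
    required = rule.required_classes
    # Index modified positions once; site density is sparse relative to L.
    top_ok = {
        pos
        for (pos, strand), cls in genome.mods.items()
        if strand == TOP and cls in required
    }
    bottom_ok = {
        pos
        for (pos, strand), cls in genome.mods.items()
        if strand == BOTTOM and cls in required
    }
    for p in sorted(top_ok):
        q = p + s
        if q >= L:
            continue
        if q in bottom_ok:
            sites.append(
                RecognitionSite(
                    genome.id, p, (genome.mods[(p, TOP)], genome.mods[(q, BOTTOM)])
                )
            )
    return sites


def cut_positions(
    site: RecognitionSite, rule: RecognitionRule, genome_length: int | None = None
) -> DuplexCut:
    """Nick boundaries of a cut at ``site``: the top strand is nicked ``u``
    intervening bases downstream of the modified C, the bottom strand ``v``
    intervening bases upstream of the distal anchor."""
    u = rule.offset_modified
    top_nick = site.p + u + 1
    bottom_nick = top_nick - rule.overhang
    if genome_length is not None:
        for b in (top_nick, bottom_nick):
            if not 0 <= b <= genome_length:
                raise ValueError(
                    f"nick boundary {b} outside [0, {genome_length}] for site "
                    f"at {site.p}"
                )
    return DuplexCut(top_nick=top_nick, bottom_nick=bottom_nick)


def _chemistry_pair(rule: RecognitionRule) -> tuple[EndChemistry, EndChemistry]:
    """(right end of the upstream fragment, left end of the downstream one)."""
    o = rule.overhang
    if o == 0:
        return BLUNT_END, BLUNT_END
    if o > 0:  # 3' overhang: upstream fragment protrudes its top strand
        return (
            EndChemistry("overhang", o, THREE_PRIME, TOP),
            EndChemistry("overhang", o, THREE_PRIME, BOTTOM),
        )
    return (
        EndChemistry("overhang", -o, FIVE_PRIME, BOTTOM),
        EndChemistry("overhang", -o, FIVE_PRIME, TOP),
    )


def simulate_digest(
    genome: ModifiedGenome, rule: RecognitionRule, seed: int
) -> list[Fragment]:
    """Cut every recognized site independently and return the fragments.

    Each site is cut with probability equal to the minimum of its two
    half-site class efficiencies. Accepted cuts are applied greedily left to
    right; a cut whose top nick lies closer than ``|o| + 1`` to the previous
    accepted cut's is skipped, as are cuts whose staggered region would touch
    a genome end. ``k`` accepted cuts on a linear genome yield ``k + 1``
    fragments whose internal ends carry the rule's overhang chemistry.
    """
    sites = find_recognition_sites(genome, rule)
    rng = derive_rng(seed, "digest")
    draws = rng.random(len(sites))
    L = len(genome.seq)
    o = rule.overhang
    cuts: list[DuplexCut] = []
    last_top: int | None = None
    for site, x in zip(sites, draws):
        if x >= rule.site_efficiency(site):
            continue
        cut = cut_positions(site, rule)
        lo, hi = min(cut.top_nick, cut.bottom_nick), max(cut.top_nick, cut.bottom_nick)
        if lo <= 0 or hi >= L:
            continue  # cutting at the very end leaves no fragment
        if last_top is not None and cut.top_nick - last_top < abs(o) + 1:
            continue
        cuts.append(cut)
        last_top = cut.top_nick
    logger.debug("digest: %d sites, %d accepted cuts", len(sites), len(cuts))

    right_chem, left_chem = _chemistry_pair(rule)
    fragments: list[Fragment] = []
    prev_boundary = 0
    prev_left = BLUNT_END
    for cut in cuts:
        core_end = min(cut.top_nick, cut.bottom_nick)
        fragments.append(
            Fragment(genome.id, prev_boundary, core_end, prev_left, right_chem)
        )
        prev_boundary = max(cut.top_nick, cut.bottom_nick)
        prev_left = left_chem
    fragments.append(Fragment(genome.id, prev_boundary, L, prev_left, BLUNT_END))
    return fragments


def end_repair(fragment: Fragment) -> RepairedInterval:
    """Blunt a fragment the way library prep does.

    3' overhangs are chewed back to the duplex core; 5' overhangs are filled
    in, extending the mapped interval over the protrusion; blunt ends are
    unchanged. dA tailing and adapter ligation are length-neutral here (they
    are trimmed before mapping in real pipelines).
    """
    start, end = fragment.start, fragment.end
    if fragment.left_end.polarity == FIVE_PRIME:
        start -= fragment.left_end.length
    if fragment.right_end.polarity == FIVE_PRIME:
        end += fragment.right_end.length
    return RepairedInterval(fragment.genome_id, start, end)


def emit_read_pairs(
    intervals: list[RepairedInterval],
    genome: ModifiedGenome,
    read_len: int,
    seed: int,
) -> list[ReadPair]:
    """Error-free paired-end reads from the outer ends of each interval.

    Mate 1 is the first ``min(read_len, len)`` bases of the interval on the
    top strand; mate 2 is the reverse complement of the last such bases. Truth
    coordinates are encoded in the read name. ``seed`` is accepted for
    interface stability (an error model would consume it) but the default
    emission is deterministic.
    """
    if read_len < 1:
        raise ValueError(f"read_len must be >= 1, got {read_len}")
    del seed  # error-free emission draws nothing
    pairs: list[ReadPair] = []
    for i, iv in enumerate(intervals):
        n = min(read_len, len(iv))
        sub1 = genome.seq[iv.start : iv.start + n]
        sub2 = reverse_complement(genome.seq[iv.end - n : iv.end])
        name = f"frag_{i}_{iv.genome_id}_{iv.start}_{iv.end}"
        pairs.append(ReadPair(name, sub1, sub2))
    return pairs


# ---------------------------------------------------------------------------
# Serialization: fragments as BED3 plus an end-chemistry TSV sidecar,
# repaired intervals as BED3, reads as FASTQ.
# ---------------------------------------------------------------------------


def write_fragments_bed(fragments: list[Fragment], bed_path, chem_path) -> None:
    with open(bed_path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.genome_id}\t{frag.start}\t{frag.end}\n")
    with open(chem_path, "w") as fh:
        fh.write("fragment\tside\tpolarity\tlength\tprotruding_strand\n")
        for i, frag in enumerate(fragments):
            for side, chem in (("left", frag.left_end), ("right", frag.right_end)):
                fh.write(
                    f"{i}\t{side}\t{chem.polarity}\t{chem.length}\t"
                    f"{chem.protruding_strand or '.'}\n"
                )


def write_intervals_bed(intervals: list[RepairedInterval], bed_path) -> None:
    with open(bed_path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.genome_id}\t{iv.start}\t{iv.end}\n")


def read_intervals_bed(bed_path) -> list[RepairedInterval]:
    out: list[RepairedInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 columns")
            out.append(
                RepairedInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return out


def write_fastq_pairs(pairs: list[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{'I' * len(pair.mate1)}\n")
            f2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{'I' * len(pair.mate2)}\n")
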