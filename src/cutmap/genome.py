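"""Synthetic modified genomes.

Generates seeded random phage-like genomes and attaches a per-position,
per-strand cytosine-modification track over the classes {C, m5C, hm5C, ghm5C}.
T-even phages replace genomic cytosine with 5-hydroxymethylcytosine (hm5C),
usually further glucosylated (ghm5C); the default scheme therefore marks every
cytosine on both strands.

Coordinate conventions used throughout the package:

* sequences are 0-based, half-open;
* a *boundary* ``b`` is the inter-base position between base ``b - 1`` and
  base ``b``, so nick boundaries are integers in ``[0, L]``;
* bottom-strand positions are keyed by the top-strand coordinate of the
  paired base — a bottom-strand cytosine sits wherever the top strand reads G.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TOP",
    "BOTTOM",
    "ModClass",
    "ModificationScheme",
    "ModifiedGenome",
    "generate_genome",
    "apply_modification_scheme",
    "write_modified_genome",
    "read_modified_genome",
    "derive_rng",
    "complement",
    "reverse_complement",
    "TrackParseError",
]

TOP = "top"
BOTTOM = "bottom"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Derive an independent RNG stream for a named pipeline stage.

    One integer master seed drives the whole pipeline; each stage draws from a
    stream keyed by ``(master_seed, crc32(stage))`` so that reordering stages
    cannot silently couple their randomness.
    """
    import zlib

    return np.random.default_rng([int(master_seed), zlib.crc32(stage.encode())])


class ModClass(str, enum.Enum):
    """Cytosine C5 modification state.

    ``hm5C`` (5-hydroxymethylcytosine) and ``ghm5C`` (its beta-glucosylated
    derivative) are the classes cleaved by the modeled endonuclease; ``C`` and
    ``m5C`` are refractory.
    """

    C = "C"
    m5C = "m5C"
    hm5C = "hm5C"
    ghm5C = "ghm5C"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes cleavable by the default recognition rule.
CLEAVABLE_CLASSES = frozenset({ModClass.hm5C, ModClass.ghm5C})

_STRANDS = (TOP, BOTTOM)


class TrackParseError(ValueError):
    """Raised for a malformed modification-track line; carries the line number."""


@dataclass(frozen=True)
class ModificationScheme:
    """How to paint a modification track onto a genome.

    mode
        ``none`` clears the track; ``all`` marks every strand-wise cytosine;
        ``fraction`` marks a seeded Bernoulli subset; ``explicit`` marks the
        listed ``(position, strand)`` sites.
    """

    mode: str
    mod_class: ModClass = ModClass.hm5C
    fraction: float | None = None
    sites: tuple[tuple[int, str], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "all", "fraction", "explicit"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if (self.mode == "fraction") != (self.fraction is not None):
            raise ValueError("fraction is required iff mode='fraction'")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if (self.mode == "explicit") != (self.sites is not None):
            raise ValueError("sites are required iff mode='explicit'")


@dataclass
class ModifiedGenome:
    """A double-stranded sequence plus its cytosine-modification track.

    ``mods`` maps ``(position, strand)`` to a :class:`ModClass` and is defined
    only where the stated strand actually carries a cytosine (top-strand C, or
    bottom-strand C where the top strand reads G). An absent key means an
    unmodified cytosine.
    """

    id: str
    seq: str
    mods: dict[tuple[int, str], ModClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
        for (pos, strand) in self.mods:
            self._check_cytosine(pos, strand)

    def _check_cytosine(self, pos: int, strand: str) -> None:
        if strand not in _STRANDS:
            raise ValueError(f"unknown strand {strand!r} at position {pos}")
        if not 0 <= pos < len(self.seq):
            raise ValueError(f"position {pos} outside [0, {len(self.seq)})")
        want = "C" if strand == TOP else "G"
        if self.seq[pos] != want:
            raise ValueError(
                f"({pos}, {strand}) is not a cytosine on that strand "
                f"(top base is {self.seq[pos]!r})"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModifiedGenome):
            return NotImplemented
        return (
            self.id == other.id
            and self.seq == other.seq
            and self.mods == other.mods
        )

    def cytosine_sites(self) -> list[tuple[int, str]]:
        """All strand-wise cytosines, sorted by (position, top-before-bottom)."""
        out: list[tuple[int, str]] = []
        for i, b in enumerate(self.seq):
            if b == "C":
                out.append((i, TOP))
            elif b == "G":
                out.append((i, BOTTOM))
        return out

    def mod_class_at(self, pos: int, strand: str) -> ModClass | None:
        """Modification class at a strand-wise cytosine, or None if untracked."""
        return self.mods.get((pos, strand))

    def reverse_complement(self) -> "ModifiedGenome":
        """The same molecule read from the other end (coordinates remapped)."""
        L = len(self.seq)
        flipped = {
            (L - 1 - pos, BOTTOM if strand == TOP else TOP): cls
            for (pos, strand), cls in self.mods.items()
        }
        return ModifiedGenome(self.id, reverse_complement(self.seq), flipped)


def generate_genome(
    length: int, gc: float, seed: int, genome_id: str = "synthetic"
) -> ModifiedGenome:
    """Generate an i.i.d. random genome with the given GC content.

    Each base is drawn independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1 - gc)/2; the modification track starts empty.
    """
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    rng = derive_rng(seed, "genome")
    bases = rng.choice(
        np.array(list("ACGT")),
        size=length,
        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
    )
    return ModifiedGenome(genome_id, "".join(bases))


def apply_modification_scheme(
    genome: ModifiedGenome, scheme: ModificationScheme
) -> ModifiedGenome:
    """Return a copy of ``genome`` with its track rewritten per ``scheme``."""
    if scheme.mode == "none":
        return replace(genome, mods={})
    if scheme.mode == "all":
        mods = {site: scheme.mod_class for site in genome.cytosine_sites()}
        return replace(genome, mods=mods)
    if scheme.mode == "fraction":
        sites = genome.cytosine_sites()
        rng = derive_rng(scheme.seed, "modscheme")
        keep = rng.random(len(sites)) < scheme.fraction
        mods = {site: scheme.mod_class for site, k in zip(sites, keep) if k}
        return replace(genome, mods=mods)
    # explicit
    mods: dict[tuple[int, str], ModClass] = {}
    for pos, strand in scheme.sites:  # type: ignore[union-attr]
        genome._check_cytosine(pos, strand)
        mods[(pos, strand)] = scheme.mod_class
    return replace(genome, mods=mods)


# ---------------------------------------------------------------------------
# Serialization: FASTA for the sequence, BED6+1 for the modification track.
# Track columns: chrom, start, start+1, name=mod class, score=0, strand
# (+ = top, - = bottom), and column 7 repeating the mod class.
# ---------------------------------------------------------------------------

_STRAND_TO_BED = {TOP: "+", BOTTOM: "-"}
_BED_TO_STRAND = {"+": TOP, "-": BOTTOM}


def _canonical_track_order(item: tuple[tuple[int, str], ModClass]):
    (pos, strand), _ = item
    return (pos, 0 if strand == TOP else 1)


def write_modified_genome(
    genome: ModifiedGenome, fasta_path, track_path
) -> None:
    """Write the sequence as FASTA and the track as BED6+1 (canonical order)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([record], fh, "fasta")
    with open(track_path, "w") as fh:
        for (pos, strand), cls in sorted(
            genome.mods.items(), key=_canonical_track_order
        ):
            fh.write(
                f"{genome.id}\t{pos}\t{pos + 1}\t{cls.value}\t0\t"
                f"{_STRAND_TO_BED[strand]}\t{cls.value}\n"
            )


def read_modified_genome(fasta_path, track_path) -> ModifiedGenome:
    """Inverse of :func:`write_modified_genome`; validates every track line."""
    from Bio import SeqIO

    record = next(SeqIO.parse(fasta_path, "fasta"))
    genome = ModifiedGenome(record.id, str(record.seq).upper())
    mods: dict[tuple[int, str], ModClass] = {}
    with open(track_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise TrackParseError(
                    f"{track_path}:{lineno}: expected 7 tab-separated columns"
                )
            chrom, start, end, name, _score, strand_sym, cls_name = fields[:7]
            if chrom != genome.id:
                raise TrackParseError(
                    f"{track_path}:{lineno}: chrom {chrom!r} != {genome.id!r}"
                )
            if strand_sym not in _BED_TO_STRAND:
                raise TrackParseError(
                    f"{track_path}:{lineno}: bad strand {strand_sym!r}"
                )
            try:
                pos = int(start)
                cls = ModClass(cls_name)
            except ValueError as exc:
                raise TrackParseError(f"{track_path}:{lineno}: {exc}") from exc
            if int(end) != pos + 1:
                raise TrackParseError(
                    f"{track_path}:{lineno}: track entries must be 1-bp intervals"
                )
            strand = _BED_TO_STRAND[strand_sym]
            try:
                genome._check_cytosine(pos, strand)
            except ValueError as exc:
                raise TrackParseError(f"{track_path}:{lineno}: {exc}") from exc
            mods[(pos, strand)] = cls
    genome.mods = mods
    return genome
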