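"""Overhang and nick inference from mapped fragment intervals.

After staggered cleavage and end repair, the mapped footprints of two
fragments flanking one cut are no longer complementary: chew-back of a 3'
overhang leaves a positive gap between the upstream fragment's mapped end and
the downstream fragment's mapped start, fill-in of a 5' overhang leaves a
negative one, and blunt cuts leave abutting intervals. The signed gap mode
therefore encodes overhang length and polarity, and each correctly paired
(end, start) couple pins both nick boundaries of the cut to single-base
resolution.

Gap sign convention (load-bearing): for an upstream mapped end ``e`` and a
downstream mapped start ``s`` in half-open coordinates, ``g = s - e``.
Abutting blunt fragments give ``g = 0``; a chewed o-nt 3' overhang gives
``g = +o``; a filled o-nt 5' overhang gives ``g = -o``.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .digest import FIVE_PRIME, THREE_PRIME, RepairedInterval

__all__ = [
    "BLUNT",
    "GapHistogram",
    "OverhangCall",
    "NickPileup",
    "NoCleavageError",
    "gap_distribution",
    "infer_overhang",
    "reconstruct_nicks",
    "write_gap_histogram",
    "read_gap_histogram",
    "write_pileup",
    "read_pileup",
]

logger = logging.getLogger(__name__)

BLUNT = "blunt"


class NoCleavageError(ValueError):
    """No fragment-end pairs were observed — nothing was cleaved."""


@dataclass
class GapHistogram:
    """Counts of signed adjacent-end distances within a pairing window."""

    counts: dict[int, int]
    window: int

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class OverhangCall:
    """Inferred overhang: length in nt, polarity, and modal support."""

    length: int
    polarity: str  # "3'" | "5'" | "blunt"
    support: float

    def __post_init__(self) -> None:
        if (self.polarity == BLUNT) != (self.length == 0):
            raise ValueError("polarity 'blunt' iff length 0")

    @property
    def signed_gap(self) -> int:
        """The mapped-interval gap this chemistry produces."""
        if self.polarity == THREE_PRIME:
            return self.length
        if self.polarity == FIVE_PRIME:
            return -self.length
        return 0


@dataclass
class NickPileup:
    """Reconstructed cut loci and per-boundary nick counts.

    ``loci`` maps ``(top_nick, bottom_nick)`` to a support count; the two
    boundaries at one locus differ by the called overhang. ``flagged`` counts
    end/start pairs that fell inside the pairing window but at a gap
    inconsistent with the overhang call.
    """

    loci: dict[tuple[int, int], int] = field(default_factory=dict)
    flagged: int = 0

    @property
    def top_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (top, _), n in self.loci.items():
            out[top] = out.get(top, 0) + n
        return out

    @property
    def bottom_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (_, bottom), n in self.loci.items():
            out[bottom] = out.get(bottom, 0) + n
        return out

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _dedupe(intervals) -> list[tuple[int, int]]:
    """Collapse duplicate fragments (PCR duplicates) to unique intervals."""
    seen = {(iv.start, iv.end) if isinstance(iv, RepairedInterval) else tuple(iv)
            for iv in intervals}
    return sorted(seen)


def _window_pairs(intervals, window: int):
    """Yield (e, s) for every end e of one interval and start s of another
    with |s - e| <= window."""
    uniq = _dedupe(intervals)
    starts = [iv[0] for iv in uniq]
    for j, (_, e) in enumerate(uniq):
        lo = bisect_left(starts, e - window)
        hi = bisect_right(starts, e + window)
        for i in range(lo, hi):
            if i == j:
                continue
            yield e, starts[i]


def gap_distribution(intervals, window: int = 10) -> GapHistogram:
    """Histogram of signed end-to-start distances between distinct intervals.

    Duplicate intervals are collapsed first; every (end, start) pair of
    distinct intervals within ``window`` contributes one count at
    ``g = start - end``.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    counts: dict[int, int] = {}
    for e, s in _window_pairs(intervals, window):
        g = s - e
        counts[g] = counts.get(g, 0) + 1
    return GapHistogram(counts=counts, window=window)


def infer_overhang(hist: GapHistogram) -> OverhangCall:
    """Call overhang length and polarity from the modal signed gap.

    Ties are broken toward smaller |g|, then toward the positive sign.
    A positive mode means a 3' overhang (chewed back), a negative mode a 5'
    overhang (filled in), zero means blunt cleavage.
    """
    if not hist.counts:
        raise NoCleavageError("empty gap histogram: no cleavage detected")
    g_star = min(hist.counts, key=lambda g: (-hist.counts[g], abs(g), g < 0))
    support = hist.counts[g_star] / hist.n_pairs
    if g_star > 0:
        return OverhangCall(g_star, THREE_PRIME, support)
    if g_star < 0:
        return OverhangCall(-g_star, FIVE_PRIME, support)
    return OverhangCall(0, BLUNT, support)


def reconstruct_nicks(
    intervals, call: OverhangCall, window: int = 10
) -> NickPileup:
    """Recover dual-strand nick boundaries from repaired intervals.

    Under 3' chemistry the downstream fragment start is unshifted (it is the
    top-strand nick) while the upstream fragment end was chewed back by the
    overhang and sits exactly at the bottom-strand nick; under 5' chemistry
    the roles mirror. In all chemistries a correctly paired (end ``e``, start
    ``s``) couple with ``s - e`` equal to the expected gap yields the locus
    ``top = s``, ``bottom = e``. Pairs inside the window at any other gap are
    flagged and excluded.
    """
    expected = call.signed_gap
    pileup = NickPileup()
    for e, s in _window_pairs(intervals, window):
        if s - e == expected:
            key = (s, e)
            pileup.loci[key] = pileup.loci.get(key, 0) + 1
        else:
            pileup.flagged += 1
    logger.debug(
        "reconstruct_nicks: %d loci, %d flagged pairs", pileup.n_loci, pileup.flagged
    )
    return pileup


# ---------------------------------------------------------------------------
# Serialization: histogram TSV, pileup loci TSV + per-boundary BED,
# diagnostics JSON.
# ---------------------------------------------------------------------------


def write_gap_histogram(hist: GapHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pairing_window\t{hist.window}\n")
        fh.write("gap\tcount\n")
        for g in sorted(hist.counts):
            fh.write(f"{g}\t{hist.counts[g]}\n")


def read_gap_histogram(path) -> GapHistogram:
    counts: dict[int, int] = {}
    window = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# pairing_window"):
                window = int(line.split("\t")[1])
            elif line and not line.startswith(("#", "gap\t")):
                g, n = line.split("\t")
                counts[int(g)] = int(n)
    return GapHistogram(counts=counts, window=window)


def write_pileup(
    pileup: NickPileup, genome_id: str, loci_path, bed_path, diagnostics_path
) -> None:
    """Loci TSV (top, bottom, count), per-boundary BED (boundary rendered as a
    0-length feature, strand + = top nick, - = bottom nick), diagnostics JSON."""
    with open(loci_path, "w") as fh:
        fh.write("top_nick\tbottom_nick\tcount\n")
        for (top, bottom), n in sorted(pileup.loci.items()):
            fh.write(f"{top}\t{bottom}\t{n}\n")
    with open(bed_path, "w") as fh:
        rows = [
            (b, "+", n) for b, n in sorted(pileup.top_counts.items())
        ] + [(b, "-", n) for b, n in sorted(pileup.bottom_counts.items())]
        for b, strand, n in sorted(rows):
            fh.write(f"{genome_id}\t{b}\t{b}\tnick\t{n}\t{strand}\n")
    with open(diagnostics_path, "w") as fh:
        json.dump(
            {
                "n_loci": pileup.n_loci,
                "total_support": sum(pileup.loci.values()),
                "flagged_pairs": pileup.flagged,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_pileup(loci_path) -> NickPileup:
    pileup = NickPileup()
    with open(loci_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("top_nick"):
                continue
            top, bottom, n = line.split("\t")
            pileup.loci[(int(top), int(bottom))] = int(n)
    return pileup
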