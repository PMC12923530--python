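"""Flank sequence logos, consensus calling and rule-parameter recovery.

The flank position-frequency matrix (PFM) is anchored on the top-strand nick
boundary: columns -W..-1 are the bases immediately left of the nick (-1
adjacent) and +1..+W the bases to its right, accumulated over loci weighted by
pileup support. Because the bipartite site is rotationally symmetric, the
bottom-strand logo is the reverse complement of the top-strand one and is not
computed separately.

With the default enzyme geometry on an all-modified genome the PFM shows two
fixed anchors — C at column -12 and G at column +10 — and background
frequencies everywhere else, which the consensus caller renders as
``CN11/N9G``: the modified C, 11 unconstrained bases, the top-strand nick
(``/``), 9 unconstrained bases, and the G paired with the second modified C.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import BOTTOM, TOP, ModClass, ModifiedGenome
from .ends import NickPileup

__all__ = [
    "BASES",
    "FlankPFM",
    "ConsensusModel",
    "RuleEstimate",
    "NoSitesError",
    "flank_pfm",
    "column_information",
    "consensus_call",
    "infer_rule_parameters",
    "write_pfm",
    "read_pfm",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class NoSitesError(ValueError):
    """Raised when a PFM is requested from an empty pileup."""


@dataclass
class FlankPFM:
    """Per-column base probabilities around the top-strand nick.

    ``probs`` has shape (2W, 4) over A, C, G, T; row ``W + c`` holds column
    ``c`` for c in -W..-1 and row ``W + c - 1`` holds column ``c`` for
    c in +1..+W (there is no column 0 — the nick is a boundary, not a base).
    """

    window: int
    probs: np.ndarray
    n_sites: int
    n_dropped: int = 0

    def columns(self) -> list[int]:
        W = self.window
        return list(range(-W, 0)) + list(range(1, W + 1))

    def _row(self, column: int) -> int:
        W = self.window
        if -W <= column <= -1:
            return W + column
        if 1 <= column <= W:
            return W + column - 1
        raise IndexError(f"column {column} outside ±{W} (and 0 is the nick)")

    def column_probs(self, column: int) -> np.ndarray:
        return self.probs[self._row(column)]

    def p(self, column: int, base: str) -> float:
        return float(self.column_probs(column)[_BASE_INDEX[base]])


@dataclass
class ConsensusModel:
    """Called consensus with recovered site geometry.

    ``consensus`` is run-length rendered over {A, C, G, T, N} with a single
    ``/`` marking the top-strand nick (e.g. ``CN11/N9G``); ``u_hat``/``v_hat``
    count intervening bases between the nick and the nearest conserved column
    on each side, and ``s_hat = u_hat + v_hat + 1`` when both anchors exist.
    """

    consensus: str
    conserved: list[tuple[int, str, float]] = field(default_factory=list)
    u_hat: int | None = None
    v_hat: int | None = None
    s_hat: int | None = None
    overhang_hat: int | None = None
    flagged: bool = False


@dataclass(frozen=True)
class RuleEstimate:
    """Modal recognition-rule geometry recovered against a ground-truth track."""

    u: int
    v: int
    s: int
    n_loci: int = 0
    n_excluded: int = 0


def flank_pfm(
    pileup: NickPileup, genome: ModifiedGenome, window: int = 20
) -> FlankPFM:
    """Base-count matrix over the 2W bases flanking each top-strand nick.

    Counts are accumulated over top-strand nick boundaries on the top-strand
    sequence, weighted by pileup support, with no pseudocounts. Nicks closer
    than ``window`` to a genome end are dropped and counted in ``n_dropped``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(genome.seq)
    counts = np.zeros((2 * window, 4))
    used = 0
    dropped = 0
    for boundary, weight in sorted(pileup.top_counts.items()):
        if boundary - window < 0 or boundary + window > L:
            dropped += weight
            continue
        flank = genome.seq[boundary - window : boundary + window]
        for row, base in enumerate(flank):
            counts[row, _BASE_INDEX[base]] += weight
        used += weight
    if used == 0:
        raise NoSitesError("no nick has a full flanking window: empty PFM")
    probs = counts / counts.sum(axis=1, keepdims=True)
    return FlankPFM(window=window, probs=probs, n_sites=used, n_dropped=dropped)


def column_information(
    pfm: FlankPFM, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-column relative-entropy information in bits.

    ``I = sum_b p_b log2(p_b / q_b)`` with ``0 log 0 := 0``; under a uniform
    background this equals ``2 - H(p)``, the usual logo height.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    p = pfm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / background), 0.0)
    return terms.sum(axis=1)


def _render_run(base: str, length: int) -> str:
    if base != "N":
        return base * length
    return "N" if length == 1 else f"N{length}"


def _rle(symbols: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(symbols):
        j = i
        while j < len(symbols) and symbols[j] == symbols[i]:
            j += 1
        out.append(_render_run(symbols[i], j - i))
        i = j
    return "".join(out)


def consensus_call(pfm: FlankPFM, threshold: float = 0.9) -> ConsensusModel:
    """Call the consensus string and site geometry from a flank PFM.

    A column is conserved iff its maximal base frequency reaches ``threshold``;
    all other columns render as N, with N runs length-compressed. The rendered
    string spans the outermost conserved columns and always contains the nick
    marker ``/``. Offsets count intervening bases: ``u_hat`` is the number of
    N columns between the nearest conserved column left of the nick and the
    nick itself, ``v_hat`` likewise on the right.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    conserved: list[tuple[int, str, float]] = []
    for col in pfm.columns():
        p = pfm.column_probs(col)
        imax = int(np.argmax(p))
        if p[imax] >= threshold:
            conserved.append((col, BASES[imax], float(p[imax])))
    W = pfm.window
    if not conserved:
        return ConsensusModel(
            consensus=f"N{W}/N{W}" if W > 1 else "N/N", flagged=True
        )
    by_col = {c: b for c, b, _ in conserved}
    left_cols = [c for c in by_col if c < 0]
    right_cols = [c for c in by_col if c > 0]
    lo = min(by_col)
    hi = max(by_col)
    left = [by_col.get(c, "N") for c in range(min(lo, -1) if left_cols else 0, 0)]
    right = [by_col.get(c, "N") for c in range(1, (max(hi, 1) + 1) if right_cols else 1)]
    consensus = _rle(left) + "/" + _rle(right)
    u_hat = (-max(left_cols) - 1) if left_cols else None
    v_hat = (min(right_cols) - 1) if right_cols else None
    s_hat = u_hat + v_hat + 1 if (u_hat is not None and v_hat is not None) else None
    overhang = u_hat - v_hat if s_hat is not None else None
    return ConsensusModel(
        consensus=consensus,
        conserved=conserved,
        u_hat=u_hat,
        v_hat=v_hat,
        s_hat=s_hat,
        overhang_hat=overhang,
        flagged=s_hat is None,
    )


def infer_rule_parameters(
    pileup: NickPileup,
    genome: ModifiedGenome,
    s_max: int = 64,
    classes: frozenset | None = None,
) -> RuleEstimate:
    """Recover (u, v, s) against the ground-truth modification track.

    For each reconstructed locus ``(top, bottom)`` the two anchors of the
    generating site are mirror-symmetric about the cut center: an upstream
    top-strand modified C at ``q = top - u' - 1`` pairs with a downstream
    bottom-strand modified partner at ``r = bottom + u'`` (so that
    ``q + r = top + bottom - 1``), for the same intervening count ``u'`` on
    each modified strand. The smallest-span anchor pair within ``s_max`` wins;
    loci with no pair in range are excluded and counted. The modal values of
    u, v and the anchor spacing s over supported loci are returned — exact
    per locus when only true sites carry modifications.
    """
    if not pileup.loci:
        raise NoSitesError("empty pileup: no loci to type")
    if not genome.mods:
        raise NoSitesError("genome carries an empty modification track")
    L = len(genome.seq)
    u_counts: dict[int, int] = {}
    v_counts: dict[int, int] = {}
    s_counts: dict[int, int] = {}
    excluded = 0
    typed = 0
    for (top, bottom), weight in sorted(pileup.loci.items()):
        o = top - bottom
        found = None
        u_cand = max(0, o)
        while True:
            v_cand = u_cand - o
            span = u_cand + v_cand + 1
            if span > s_max:
                break
            q = top - u_cand - 1
            r = bottom + u_cand
            if q >= 0 and r < L:
                cls_q = genome.mods.get((q, TOP))
                cls_r = genome.mods.get((r, BOTTOM))
                ok_q = cls_q is not None and (classes is None or cls_q in classes)
                ok_r = cls_r is not None and (classes is None or cls_r in classes)
                if ok_q and ok_r:
                    found = (u_cand, v_cand, span)
                    break
            u_cand += 1
        if found is None:
            excluded += 1
            continue
        u, v, s = found
        u_counts[u] = u_counts.get(u, 0) + weight
        v_counts[v] = v_counts.get(v, 0) + weight
        s_counts[s] = s_counts.get(s, 0) + weight
        typed += 1
    if not u_counts:
        raise NoSitesError(
            f"no locus carries a tracked modification within s_max={s_max}"
        )
    if excluded:
        logger.warning(
            "infer_rule_parameters: %d loci had no anchor pair within s_max=%d",
            excluded,
            s_max,
        )
    mode = lambda d: min(d, key=lambda k: (-d[k], k))  # noqa: E731
    return RuleEstimate(
        u=mode(u_counts),
        v=mode(v_counts),
        s=mode(s_counts),
        n_loci=typed,
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Serialization: PFM / information tracks as TSV (logo-ready), consensus and
# recovered parameters as JSON.
# ---------------------------------------------------------------------------


def write_pfm(pfm: FlankPFM, path, background: np.ndarray | None = None) -> None:
    """Logo-ready TSV: column index, per-base probabilities, information bits."""
    import pandas as pd

    bits = column_information(pfm, background)
    df = pd.DataFrame(
        {
            "column": pfm.columns(),
            **{b: pfm.probs[:, i] for i, b in enumerate(BASES)},
            "bits": bits,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pfm(path) -> FlankPFM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    W = len(df) // 2
    probs = df[list(BASES)].to_numpy(dtype=float)
    return FlankPFM(window=W, probs=probs, n_sites=1)
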