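"""Downstream quantifications: cut-site span in Å, coverage depletion, and
efficiency-of-plating statistics.

The 21-bp spacing between the two modified cytosines of a bipartite site
converts, at the canonical B-DNA helical rise of 3.4 Å/bp, to a physical span
of ~71 Å — the number that frames whether one enzyme dimer (whose two
modified-cytosine pockets sit ~53 Å apart) or a larger assembly engages both
half-sites. Coverage depletion compares normalized read densities between a
digestible target genome and an undigestible control; efficiency of plating
summarizes phage-defense strength from serial-dilution plaque counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "B_DNA_RISE_ANGSTROM",
    "REFERENCE_DISTANCES",
    "GeometryReport",
    "CoverageComparison",
    "PlateCounts",
    "PlatingResult",
    "bp_to_angstrom",
    "geometry_report",
    "depletion_fold",
    "binned_read_density",
    "coverage_comparison",
    "efficiency_of_plating",
]

#: Axial length per base pair of B-form DNA.
B_DNA_RISE_ANGSTROM = 3.4

#: Structural yardsticks carried as annotations only (nothing here computes
#: atomic distances): the modified-cytosine pocket separation within one
#: enzyme dimer, and the minimum separation between pockets of different
#: dimers in the tetramer.
REFERENCE_DISTANCES = {
    "intra_dimer_angstrom": 53.0,
    "inter_dimer_min_angstrom": 80.0,
}


def bp_to_angstrom(n_bp: int, rise: float = B_DNA_RISE_ANGSTROM) -> float:
    """Physical span of ``n_bp`` base pairs along the helix axis."""
    if n_bp < 0:
        raise ValueError(f"n_bp must be non-negative, got {n_bp}")
    if rise <= 0:
        raise ValueError(f"rise must be positive, got {rise}")
    return n_bp * rise


@dataclass(frozen=True)
class GeometryReport:
    spacing_bp: int
    rise_per_bp: float
    span_angstrom: float
    reference_distances: dict = field(
        default_factory=lambda: dict(REFERENCE_DISTANCES)
    )


def geometry_report(
    spacing_bp: int, rise: float = B_DNA_RISE_ANGSTROM
) -> GeometryReport:
    return GeometryReport(
        spacing_bp=spacing_bp,
        rise_per_bp=rise,
        span_angstrom=bp_to_angstrom(spacing_bp, rise),
    )


def depletion_fold(
    target_reads_per_kb: float, control_reads_per_kb: float, pseudocount: float
) -> float:
    """Fold depletion of the target genome's read density versus the control.

    Densities should already be library-size normalized (e.g. reads per kb
    per million); the pseudocount keeps fully depleted targets finite.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if target_reads_per_kb < 0 or control_reads_per_kb < 0:
        raise ValueError("read densities must be non-negative")
    return (control_reads_per_kb + pseudocount) / (target_reads_per_kb + pseudocount)


def binned_read_density(
    intervals, genome_length: int, bin_size: int = 1000,
    library_size: int | None = None,
) -> np.ndarray:
    """Reads per kb per million, per bin, counting each interval at its start.

    ``intervals`` is anything with ``.start``/``.end`` or (start, end) pairs.
    ``library_size`` defaults to the number of intervals given; pass the
    combined total when several genomes were sequenced in one library so that
    depletion of one of them remains visible after normalization.
    """
    if genome_length < 1 or bin_size < 1:
        raise ValueError("genome_length and bin_size must be positive")
    n_bins = math.ceil(genome_length / bin_size)
    counts = np.zeros(n_bins)
    total = 0
    for iv in intervals:
        start = iv.start if hasattr(iv, "start") else iv[0]
        counts[min(start // bin_size, n_bins - 1)] += 1
        total += 1
    library_size = total if library_size is None else library_size
    if library_size == 0:
        return counts
    per_million = library_size / 1e6
    kb_per_bin = np.full(n_bins, bin_size / 1000.0)
    kb_per_bin[-1] = (genome_length - (n_bins - 1) * bin_size) / 1000.0
    return counts / kb_per_bin / per_million


@dataclass
class CoverageComparison:
    """Per-bin normalized densities for a digestible target genome and an
    undigestible control, with the genome-wide depletion fold."""

    target_density: np.ndarray
    control_density: np.ndarray
    depletion_fold: float
    pseudocount: float
    bin_size: int


def coverage_comparison(
    target_intervals,
    target_length: int,
    control_intervals,
    control_length: int,
    bin_size: int = 1000,
    pseudocount: float = 0.5,
) -> CoverageComparison:
    # Target and control genomes are treated as co-sequenced in one library,
    # so both densities are normalized by the combined read count.
    target_intervals = list(target_intervals)
    control_intervals = list(control_intervals)
    library = len(target_intervals) + len(control_intervals)
    target = binned_read_density(
        target_intervals, target_length, bin_size, library_size=library
    )
    control = binned_read_density(
        control_intervals, control_length, bin_size, library_size=library
    )
    fold = depletion_fold(float(target.mean()), float(control.mean()), pseudocount)
    return CoverageComparison(
        target_density=target,
        control_density=control,
        depletion_fold=fold,
        pseudocount=pseudocount,
        bin_size=bin_size,
    )


@dataclass(frozen=True)
class PlateCounts:
    """One titration plate: plaque count, fold dilution of the plated aliquot
    (10 means 10x diluted), and plated volume in mL."""

    plaques: int
    dilution: float
    volume_ml: float = 0.1

    def __post_init__(self) -> None:
        if self.plaques < 0:
            raise ValueError("plaque count must be non-negative")
        if self.dilution <= 0 or self.volume_ml <= 0:
            raise ValueError("dilution factor and volume must be positive")

    @property
    def titer_pfu_per_ml(self) -> float:
        return self.plaques * self.dilution / self.volume_ml


@dataclass(frozen=True)
class PlatingResult:
    """Efficiency of plating on a defended host versus a permissive control.

    ``censored`` marks a zero-plaque test plate, in which case ``eop`` is the
    upper bound obtained by substituting a count of one (reported as '<').
    """

    eop: float
    log10_reduction: float
    test_titer: float
    control_titer: float
    censored: bool = False

    def __str__(self) -> str:
        prefix = "<" if self.censored else ""
        return f"EOP {prefix}{self.eop:.3g} ({prefix}{self.log10_reduction:.2f} logs)"


def efficiency_of_plating(test: PlateCounts, control: PlateCounts) -> PlatingResult:
    """EOP = test titer / control titer, each as count x dilution / volume."""
    if control.plaques == 0:
        raise ValueError("control plate has zero plaques: titer undefined")
    censored = test.plaques == 0
    effective_test = (
        PlateCounts(1, test.dilution, test.volume_ml) if censored else test
    )
    eop = effective_test.titer_pfu_per_ml / control.titer_pfu_per_ml
    return PlatingResult(
        eop=eop,
        log10_reduction=-math.log10(eop),
        test_titer=effective_test.titer_pfu_per_ml,
        control_titer=control.titer_pfu_per_ml,
        censored=censored,
    )
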