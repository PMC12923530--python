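"""Shared fixtures and independent oracles."""

import pytest

from cutmap import (
    BOTTOM,
    TOP,
    ModClass,
    ModificationScheme,
    ModifiedGenome,
    RecognitionRule,
    RecognitionSite,
    apply_modification_scheme,
    generate_genome,
    simulate_and_infer,
)


def make_site_genome(
    u: int,
    v: int,
    n_sites: int = 55,
    seed: int = 7,
    gc: float = 0.35,
    mod_class: ModClass = ModClass.hm5C,
    margin: int = 100,
    pitch: int | None = None,
) -> ModifiedGenome:
    """Random genome carrying exactly ``n_sites`` planted bipartite sites.

    Anchor bases are forced into the sequence and only the planted anchors are
    modified, so every reconstructed locus types back to the planted rule.
    Sites are spaced far enough apart that cuts never interact and flanking
    windows never overlap a neighbour's anchors.
    """
    s = u + v + 1
    pitch = pitch or max(150, s + 90)
    length = n_sites * pitch + 2 * margin
    base = generate_genome(length, gc, seed)
    seq = list(base.seq)
    sites: list[tuple[int, str]] = []
    for k in range(n_sites):
        p = margin + k * pitch
        seq[p] = "C"
        seq[p + s] = "G"
        sites.append((p, TOP))
        sites.append((p + s, BOTTOM))
    genome = ModifiedGenome(base.id, "".join(seq))
    scheme = ModificationScheme(
        mode="explicit", mod_class=mod_class, sites=tuple(sites), seed=seed
    )
    return apply_modification_scheme(genome, scheme)


def brute_force_sites(genome: ModifiedGenome, rule: RecognitionRule):
    """Exhaustive scan oracle: test every position p independently."""
    s = rule.spacing
    L = len(genome.seq)
    out = []
    for p in range(L):
        if p + s >= L:
            continue
        if genome.seq[p] != "C" or genome.seq[p + s] != "G":
            continue
        cls_top = genome.mods.get((p, TOP))
        cls_bottom = genome.mods.get((p + s, BOTTOM))
        if cls_top in rule.required_classes and cls_bottom in rule.required_classes:
            out.append(RecognitionSite(genome.id, p, (cls_top, cls_bottom)))
    return out


@pytest.fixture(scope="session")
def default_run():
    """The desk-scale study condition: seeded 100-kb genome at GC 0.35, every
    cytosine 5hmC, default rule, full efficiency, error-free library."""
    return simulate_and_infer(seed=42)


@pytest.fixture()
def all_hm5c_10kb():
    genome = generate_genome(10_000, 0.35, seed=3)
    return apply_modification_scheme(genome, ModificationScheme(mode="all", seed=3))
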