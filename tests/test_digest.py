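"""Site scanning, staggered cleavage, end repair and read emission."""

import numpy as np
import pytest
from scipy import stats

from cutmap import (
    BOTTOM,
    TOP,
    DuplexCut,
    ModClass,
    ModificationScheme,
    ModifiedGenome,
    RecognitionRule,
    RecognitionSite,
    apply_modification_scheme,
    cut_positions,
    emit_read_pairs,
    end_repair,
    find_recognition_sites,
    reverse_complement,
    simulate_digest,
)
from cutmap.digest import write_fastq_pairs

from conftest import brute_force_sites, make_site_genome

DEFAULT = RecognitionRule()


def mer22(top_class=None, bottom_class=None):
    """A 22-mer with anchors C..0 / G..21 and A/T spacer, optionally modified."""
    seq = "C" + "ATTA" * 5 + "G"
    mods = {}
    if top_class:
        mods[(0, TOP)] = top_class
    if bottom_class:
        mods[(21, BOTTOM)] = bottom_class
    return ModifiedGenome("mer22", seq, mods)


class TestRecognitionRule:
    def test_default_geometry(self):
        assert DEFAULT.spacing == 21
        assert DEFAULT.offset_modified == 11
        assert DEFAULT.offset_other == 9
        assert DEFAULT.overhang == 2

    def test_bipartite_span_constraint_enforced(self):
        with pytest.raises(ValueError, match="u \\+ v \\+ 1"):
            RecognitionRule(spacing=20, offset_modified=11, offset_other=9)
        # decoupled geometry is an explicit opt-in for hypothetical enzymes
        RecognitionRule(
            spacing=20, offset_modified=11, offset_other=9,
            enforce_bipartite_span=False,
        )

    def test_site_efficiency_is_min_of_half_sites(self):
        rule = RecognitionRule(
            efficiency=((ModClass.hm5C, 1.0), (ModClass.ghm5C, 0.25))
        )
        site = RecognitionSite("x", 0, (ModClass.hm5C, ModClass.ghm5C))
        assert rule.site_efficiency(site) == 0.25


class TestFindRecognitionSites:
    def test_complete_site_is_found(self):
        g = mer22(ModClass.hm5C, ModClass.hm5C)
        sites = find_recognition_sites(g, DEFAULT)
        assert [s.p for s in sites] == [0]
        assert sites[0].classes == (ModClass.hm5C, ModClass.hm5C)

    def test_m5c_is_refractory(self):
        assert find_recognition_sites(mer22(ModClass.m5C, ModClass.m5C), DEFAULT) == []

    def test_single_modified_half_site_is_not_recognized(self):
        assert find_recognition_sites(mer22(top_class=ModClass.hm5C), DEFAULT) == []
        assert find_recognition_sites(mer22(bottom_class=ModClass.hm5C), DEFAULT) == []

    def test_ghm5c_is_cleavable(self):
        g = mer22(ModClass.ghm5C, ModClass.ghm5C)
        assert [s.p for s in find_recognition_sites(g, DEFAULT)] == [0]

    def test_matches_exhaustive_oracle_on_random_genome(self, all_hm5c_10kb):
        scanned = find_recognition_sites(all_hm5c_10kb, DEFAULT)
        assert scanned == brute_force_sites(all_hm5c_10kb, DEFAULT)
        assert len(scanned) > 100

    def test_no_partial_window_sites_at_genome_end(self):
        # C at 0 with the paired anchor falling exactly at the last base is a
        # site; one base shorter is not.
        g = mer22(ModClass.hm5C, ModClass.hm5C)
        assert len(find_recognition_sites(g, DEFAULT)) == 1
        truncated = ModifiedGenome("t", g.seq[:21], {(0, TOP): ModClass.hm5C})
        assert find_recognition_sites(truncated, DEFAULT) == []

    def test_site_list_invariant_under_reverse_complement(self, all_hm5c_10kb):
        L = len(all_hm5c_10kb.seq)
        fwd = {s.p for s in find_recognition_sites(all_hm5c_10kb, DEFAULT)}
        rc = all_hm5c_10kb.reverse_complement()
        rev = {s.p for s in find_recognition_sites(rc, DEFAULT)}
        assert rev == {L - 1 - (p + DEFAULT.spacing) for p in fwd}


class TestCutPositions:
    def test_default_rule_at_origin(self):
        cut = cut_positions(RecognitionSite("x", 0, (ModClass.hm5C,) * 2), DEFAULT)
        assert (cut.top_nick, cut.bottom_nick) == (12, 10)
        assert cut.overhang == 2

    def test_blunt_rule_nicks_coincide(self):
        rule = RecognitionRule.from_offsets(5, 5)
        cut = cut_positions(RecognitionSite("x", 0, (ModClass.hm5C,) * 2), rule)
        assert cut.top_nick == cut.bottom_nick == 6

    def test_translation_invariance(self):
        cut = cut_positions(RecognitionSite("x", 100, (ModClass.hm5C,) * 2), DEFAULT)
        assert (cut.top_nick, cut.bottom_nick) == (112, 110)

    def test_nick_outside_genome_rejected(self):
        site = RecognitionSite("x", 0, (ModClass.hm5C,) * 2)
        with pytest.raises(ValueError, match="nick boundary"):
            cut_positions(site, DEFAULT, genome_length=11)


class TestSimulateDigest:
    def test_one_site_yields_two_fragments_with_overhang_chemistry(self):
        frags = simulate_digest(mer22(ModClass.hm5C, ModClass.hm5C), DEFAULT, seed=0)
        assert len(frags) == 2
        left, right = frags
        assert (left.start, left.end) == (0, 10)
        assert (right.start, right.end) == (12, 22)
        assert left.left_end.is_blunt and right.right_end.is_blunt
        assert left.right_end.polarity == "3'" and left.right_end.length == 2
        assert left.right_end.protruding_strand == TOP
        assert right.left_end.polarity == "3'"
        assert right.left_end.protruding_strand == BOTTOM

    def test_no_sites_yields_whole_genome_blunt(self):
        frags = simulate_digest(mer22(), DEFAULT, seed=0)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, 22)
        assert frags[0].left_end.is_blunt and frags[0].right_end.is_blunt

    def test_partial_efficiency_matches_binomial_oracle(self):
        genome = make_site_genome(11, 9, n_sites=200, seed=21)
        rule = RecognitionRule(
            efficiency=((ModClass.hm5C, 0.5), (ModClass.ghm5C, 0.5))
        )
        n_sites = len(find_recognition_sites(genome, rule))
        assert n_sites == 200
        total_cuts = sum(
            len(simulate_digest(genome, rule, seed=s)) - 1 for s in range(400)
        )
        lo, hi = stats.binom.interval(0.999, 400 * n_sites, 0.5)
        assert lo <= total_cuts <= hi

    @pytest.mark.parametrize("u,v", [(11, 9), (9, 11), (5, 5)])
    def test_mass_conservation_under_full_digestion(self, u, v):
        # Sum of repaired lengths = L - k*o for signed overhang o = u - v.
        genome = make_site_genome(u, v, n_sites=60, seed=5)
        rule = RecognitionRule.from_offsets(u, v)
        frags = simulate_digest(genome, rule, seed=1)
        k = len(frags) - 1
        assert k == 60
        total = sum(len(end_repair(f)) for f in frags)
        assert total == len(genome.seq) - k * rule.overhang

    def test_overlapping_cuts_are_resolved_greedily(self):
        # Two sites one base apart: nicks would collide, second cut skipped.
        seq = "CC" + "A" * 19 + "GG" + "A" * 30
        g = ModifiedGenome(
            "x", seq,
            {(0, TOP): ModClass.hm5C, (1, TOP): ModClass.hm5C,
             (21, BOTTOM): ModClass.hm5C, (22, BOTTOM): ModClass.hm5C},
        )
        assert len(find_recognition_sites(g, DEFAULT)) == 2
        frags = simulate_digest(g, DEFAULT, seed=0)
        assert len(frags) == 2

    def test_determinism_under_master_seed(self):
        genome = make_site_genome(11, 9, n_sites=30, seed=8)
        rule = RecognitionRule(
            efficiency=((ModClass.hm5C, 0.7), (ModClass.ghm5C, 0.7))
        )
        assert simulate_digest(genome, rule, 123) == simulate_digest(genome, rule, 123)


class TestSpecificityGates:
    """Genomes without two engaged cleavable half-sites are never cut."""

    @pytest.mark.parametrize("mode,mod", [("none", None), ("all", ModClass.m5C)])
    def test_c_and_m5c_tracks_are_never_cut(self, all_hm5c_10kb, mode, mod):
        scheme = (
            ModificationScheme(mode="none")
            if mod is None
            else ModificationScheme(mode="all", mod_class=mod)
        )
        g = apply_modification_scheme(all_hm5c_10kb, scheme)
        frags = simulate_digest(g, DEFAULT, seed=0)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, len(g.seq))

    def test_single_modified_site_construct_is_never_cut(self):
        g = mer22(top_class=ModClass.hm5C)
        assert len(simulate_digest(g, DEFAULT, seed=0)) == 1


class TestEndRepair:
    def test_three_prime_overhang_is_chewed_back(self):
        frags = simulate_digest(mer22(ModClass.hm5C, ModClass.hm5C), DEFAULT, seed=0)
        left = end_repair(frags[0])
        assert (left.start, left.end) == (0, 10)

    def test_blunt_fragment_unchanged(self):
        frags = simulate_digest(mer22(), DEFAULT, seed=0)
        iv = end_repair(frags[0])
        assert (iv.start, iv.end) == (0, 22)

    def test_five_prime_overhang_is_filled_in(self):
        rule = RecognitionRule.from_offsets(9, 11)
        frags = simulate_digest(mer22(ModClass.hm5C, ModClass.hm5C), rule, seed=0)
        left, right = (end_repair(f) for f in frags)
        # cores are [0,10) and [12,22); fill-in extends each 2 bp over the gap
        assert (left.start, left.end) == (0, 12)
        assert (right.start, right.end) == (10, 22)


class TestEmitReadPairs:
    def test_short_interval_reads_whole_insert(self):
        from cutmap import RepairedInterval

        g = ModifiedGenome("x", "ACGTACGTAC")
        pairs = emit_read_pairs([RepairedInterval("x", 0, 10)], g, 150, seed=0)
        assert pairs[0].mate1 == "ACGTACGTAC"
        assert pairs[0].mate2 == reverse_complement("ACGTACGTAC")

    def test_long_interval_reads_outer_150mers(self):
        from cutmap import RepairedInterval

        g = ModifiedGenome("x", generate_seq(400))
        pairs = emit_read_pairs([RepairedInterval("x", 0, 300)], g, 150, seed=0)
        assert pairs[0].mate1 == g.seq[:150]
        assert pairs[0].mate2 == reverse_complement(g.seq[150:300])

    def test_fastq_emission_is_byte_identical_across_runs(self, tmp_path):
        genome = make_site_genome(11, 9, n_sites=10, seed=4)
        frags = simulate_digest(genome, DEFAULT, seed=9)
        intervals = [end_repair(f) for f in frags]
        for run in ("a", "b"):
            pairs = emit_read_pairs(intervals, genome, 150, seed=9)
            write_fastq_pairs(pairs, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()


def generate_seq(n: int) -> str:
    rng = np.random.default_rng(0)
    return "".join(rng.choice(list("ACGT"), size=n))
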