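# Methods

## Model and coordinates

All coordinates are 0-based, half-open. A *boundary* `b` is the inter-base
position between base `b − 1` and base `b`; nick boundaries are integers in
`[0, L]`. Bottom-strand features are keyed by the top-strand coordinate of the
paired base, so a bottom-strand cytosine lives wherever the top strand reads G
and no second coordinate system exists.

A recognition site at top-strand position `p` requires a cytosine at `p` and a
guanine at `p + s`, with both strand-wise cytosines carrying a cleavable
modification class. The rule parameters are linked by `s = u + v + 1`: the
site reads C, `u` unconstrained bases, the top-strand nick, `v` unconstrained
bases, G. A cut places the top nick at `p + u + 1` and the bottom nick at
`p + u + 1 − o` with signed overhang `o = u − v` (positive 3′, negative 5′,
zero blunt). The site is rotationally symmetric: each modified cytosine sees
`u` intervening bases to the nick on its own strand and `v` on the other,
which is why a single dimeric enzyme can generate it. The span constraint is
enforced at construction; a flag (`enforce_bipartite_span=False`) decouples it
for hypothetical enzymes.

## Digestion

Sites are cut independently (Bernoulli), with per-site probability equal to
the **minimum** of the two half-sites' class efficiencies — both half-sites
must engage. Defaults: hm5C = ghm5C = 1.0, everything else 0.0, which encodes
the observed substrate specificity (no activity on C or m5C, none on
single-modified-site constructs). Reduced-efficiency chemistries are
expressible through the efficiency map but have no default.

Accepted cuts are applied greedily left to right; a cut whose top nick falls
closer than `|o| + 1` to the previous accepted one is skipped (its staggered
region would overlap), as is a cut whose staggered region touches a genome
end. This resolution is deterministic given the per-site draws. Genomes are
linear; circular topology is out of scope (T-even virion DNA is linear — the
terminal redundancy of real phage genomes is likewise not modeled).

`k` accepted cuts yield `k + 1` fragments. A fragment is stored as its
double-stranded core `[start, end)` plus explicit end chemistry. End repair
maps a fragment to its blunted, mapped interval: 3′ overhangs chew back to the
core (no coordinate change for the stored core), 5′ overhangs fill in
(interval grows by the overhang on that side), blunt ends pass through. This
gives the conservation law used as a test invariant: total repaired mass is
`L − k·o` for signed `o`. Read emission is error-free 2×150-style pairs taken
from the interval's outer ends, with truth coordinates in the read names;
sequencing-error and adapter models are out of scope.

## End inference

For every mapped end `e` and start `s` of *distinct*, deduplicated intervals
with `|s − e| ≤ window`, the signed gap is `g = s − e`. Abutting blunt
fragments give 0, chewed 3′ overhangs `+o`, filled 5′ overhangs `−|o|`. The
sign convention is load-bearing: the printed "modal 2-bp distance" is `+2`
under exactly this convention. The overhang call is the modal gap (ties broken
toward smaller magnitude, then the positive sign; an empty histogram raises a
"no cleavage" signal), with support = modal count / total pairs.

The pairing window defaults to **10 bp**: real restriction overhangs are ≤ 6
nt, and a small window keeps coincidental end/start pairs rare at desk-scale
fragment densities. Property sweeps that deliberately explore overhangs up to
15 nt pass a wider window — the window is an operation parameter, not part of
the model. Duplicate intervals (PCR duplicates) are collapsed before pairing.

Nick reconstruction keeps only pairs whose gap equals the called chemistry's
expected gap; in every chemistry the locus is then `top = start`,
`bottom = end` (the chewed-back upstream end *is* the bottom nick under 3′
chemistry, and the filled upstream end under 5′ chemistry, mirrored). Pairs
inside the window at any other gap are flagged and counted in diagnostics, not
piled up. Loci are stored as paired `(top, bottom)` boundaries with support
counts; per-boundary strand-wise count maps are derived views.

## Motif inference

The flank PFM is anchored on the top-strand nick: columns −W..−1 and +1..+W
(W = 20 by default, matching the 20-bp flank extraction of standard cut-site
logos; there is no column 0, the nick is a boundary). Counts accumulate over
top-strand nicks weighted by locus support, with **no pseudocounts** by
default — exact recovery matters more than smoothing at desk scale; a
pseudocount belongs in sparse real-data use. Edge nicks without a full window
are dropped and counted. By the site's rotational symmetry the bottom-strand
logo is the reverse complement of the top-strand one and is not computed
separately. Column information is relative entropy Σ p·log2(p/q) in bits with
0·log 0 = 0.

The consensus caller marks a column conserved when its maximal base frequency
reaches the threshold (default **0.9**: in an all-modified genome the anchor
columns are exactly 1.0 while background columns sit near GC-derived
frequencies, ≤ ~0.33 at GC 0.35). Non-conserved columns render as N with runs
length-compressed, and the rendered string spans the outermost conserved
columns around the `/` nick marker. Offsets count *intervening* bases (C, then
u bases, then the nick), matching the "11 bases on the modified strand"
reading; counting to the cut base instead was considered and rejected as
inconsistent with `s = u + v + 1`.

## Rule-parameter recovery against the track

Given a locus `(top, bottom)` and the ground-truth modification track, the
generating site's two anchors are mirror-symmetric about the cut center: an
upstream top-strand modified C at `q = top − u′ − 1` pairs with a downstream
bottom-strand modified partner at `r = bottom + u′`, i.e. `q + r = top +
bottom − 1`. The recovery scans `u′` upward and keeps the smallest-span
symmetric anchor pair within `s_max` (default 64 bp, generous against real
bipartite spacers). A plain nearest-modified-C search would not work on a
genome where *every* cytosine is modified — the nearest modified C upstream of
a nick is then geometrically distributed with mode 0 — whereas the symmetric
pair constraint makes the true anchors the unique smallest pair at ~71% of
loci under GC 0.35 (a closer spurious pair needs a C and a G placed exactly
mirror-symmetrically), so the modal `(u, v, s)` over loci is exact; with
sparse (explicit-site) tracks the recovery is exact at every locus. Loci with
no anchor pair in range are excluded and counted. Modal values of u, v and s
are reported independently, with ties broken toward smaller values.

## Reporting

`bp_to_angstrom` multiplies a spacing by the helical rise, fixed at the
canonical B-DNA **3.4 Å/bp** (configurable for other helical forms); the
recovered 21-bp spacing gives 71.4 ≈ 71 Å. The geometry report carries two
structural yardsticks as annotations only (53 Å between the modified-cytosine
pockets of one enzyme dimer, > 80 Å between dimers) — the package does no
coordinate-level structural computation.

Coverage comparison treats target and control genomes as co-sequenced in one
library: per-bin reads-per-kb-per-million densities are normalized by the
*combined* read count (per-genome normalization would cancel depletion by
construction), and the depletion fold is `(control + ε)/(target + ε)` on the
genome-wide mean densities with a positive pseudocount ε.

Efficiency of plating converts each plate to PFU/mL as `count × fold-dilution
/ plated volume`; EOP is test/control and the log10 reduction its negative
logarithm. A zero-plaque test plate is reported as an upper bound with the
count substituted by 1 and an explicit censoring flag — standard titration
practice that keeps the result machine-parseable. A zero-plaque control is an
error.

## Randomness and determinism

One integer master seed drives everything. Each stage derives an independent
stream keyed by `(master_seed, crc32(stage_name))`, so stages can be reordered
or skipped without shifting each other's draws. All serializations are
canonically ordered (tracks by position/strand, loci sorted, JSON keys
sorted), so identical seeds give byte-identical FASTA/BED/TSV/FASTQ/JSON.

## Problem sizes and what the tests show

The default study condition is a 100-kb genome at GC 0.35 (a desk-scale
stand-in for a ~168-kb T-even genome, chosen for fast tests at realistic site
density) with every cytosine hm5C — matching the biology of genome-wide
cytosine substitution rather than a measured fraction, which is not available.
That condition yields ~3,000 sites and runs the full pipeline in well under a
minute; the rule-recovery sweep uses 50 planted sites per geometry on ~8-kb
genomes.

The generator emulates i.i.d. base composition, complete or Bernoulli-thinned
modification, full or partial digestion, and loss-free, error-free library
prep. It does **not** emulate sequencing errors, mapping ambiguity or
multi-mapping, fragment-size selection, chimeras, or partial end repair —
passing tests therefore demonstrate the correctness of the inference
machinery, not robustness to real-library noise. On real data the intended
entry point is deduplicated fragment intervals (BED3 derived from an external
alignment); alignment itself, and real coverage-depletion tracks, are out of
scope.
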