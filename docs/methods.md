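# Methods

## The locus model

A shufflon locus is represented as an alternating chain

```
pilV_anchor  R0  S1  R1  S2  ...  Sn  Rn  rci_anchor
```

with `n` repeat-free segment bodies `S` and `n+1` junction repeats `R`
(each ~20 bp). The anchors are the constant flanks: the 3′ end of the main
*pilV* gene and the region 5′ of *rci*. Coordinates are GFF3
(1-based, inclusive) at the file boundary and 0-based half-open
internally; this convention is asserted by the round-trip tests. Feature
sequences are stored in locus orientation (plasmid forward strand); for a
segment annotated on the minus strand the `orf_left`/`orf_right`
attributes are swapped on load so they always refer to locus-forward ends.

Validation enforces: contiguous non-overlapping features in the order
above; anchors ≥ 50 nt (shorter flanks cannot be located reliably in
error-bearing reads; configurable); repeats ≥ 10 nt, IUPAC codes allowed;
segment bodies strictly ACGT (an N in a body is rejected); and byte-exact
agreement between the reconstructed reference chain and the annotated
plasmid substring.

## Arrangement space and inversion closure

An arrangement is a signed permutation: `order` (a permutation of the
reference segment indices) plus per-position orientations. Inversion
between repeat sites `i < j` reverse-complements everything strictly
between them — interior segments and repeats move and flip, while the two
recombining sites stay in place. A consequence used throughout: the
outermost sites R0 and Rn never move, so the repeat adjacent to *pilV* is
always R0.

Two independent routes compute the space:

1. direct enumeration of all `2^n·n!` signed permutations (deterministic
   lexicographic order), matching the closed-form count for two-ORF loci;
2. breadth-first closure of the reference under all `(i, j)` inversions.

Repeat sites are treated as recombinationally equivalent (any pair can
invert) without tracking site-orientation compatibility; this reproduces
the full signed-permutation space. One-ORF segments are still
two-orientation elements at the sequence level; the closed-form count is
only claimed for two-ORF loci, and mixed loci should be summarised with
`distinct_sequence_count` (enumerate, build sequences, deduplicate), which
leaves open whether a "combination" is a distinct sequence or a distinct
variant without asserting either.

Candidate sequences per arrangement use the junction repeats propagated by
the inversion model: a full-state BFS (tracking repeat identity and sign)
assigns each arrangement the layout of the first state reaching it, so the
reference candidate is byte-identical to the annotation and every other
candidate has a physically consistent repeat layout. Junction repeats are
near-identical, so this detail is negligible for read assignment but keeps
construction exact. A bounded-search fallback substitutes the column-majority
consensus repeat at junctions; it is not expected to trigger for n ≤ 4.

## Long-read assignment

`assign_read` is a two-stage alignment, strand-symmetric by construction:

1. **Anchoring.** The last 150 nt of the pilV anchor and the first 150 nt
   of the rci anchor are located in the read (and its reverse complement)
   by semi-global alignment. A read missing both probes is `no_match`;
   missing one, or showing them out of order, is `non_spanning` — only
   reads spanning pilV→rci are informative for the whole structure.
2. **Scoring.** The read's inter-anchor core is compared with each
   candidate core (R0…Rn) by banded global edit distance;
   identity = 1 − d/max(len). The best candidate is assigned when identity
   ≥ 0.80 and it beats the runner-up by ≥ 2 % of the best score;
   otherwise the read is `ambiguous`.

Defaults (identity 0.80, anchor identity 0.80, margin 0.02) are chosen for
indel-dominated long reads; there is no standard parameterisation for
this kind of homology search, so all thresholds are exposed parameters. The band is
`max(32, 0.15·len)`, widened automatically to cover any length difference;
at default error rates (net indel drift ~5 % of length) this exceeds the
drift by an order of magnitude, and the banded kernel is validated against
a full-matrix oracle in the tests. Ambiguous reads are excluded from the
ratio denominator but reported in the totals; a read is never split and
contributes at most one assignment.

Random 300-nt segment bodies make the minimum distance between any two
candidate cores large (~50 % of a body length), so with a ~13 % error rate
misassignment is negligible and the dominant loss mode is exclusion
(anchor not found), which is arrangement-independent.

`reconstruct_from_markers` is the independent oracle: it locates the
anchors and each segment body (both orientations) separately — exact
string search first, alignment fallback — orders the hits along the read
and reads off the signed permutation directly, with no candidate sequences
involved. The two routes must agree on error-free reads.

## pilV junction typing

Because R0 never moves, the junction probe for variant `v` is
`pilV[-20:] + R0 + prefix_v[:20]`, where the prefix is the segment body 5′
end (`orf_left`) or reverse-complemented 3′ end (`orf_right`). A read is
typed to the unique probe with the best semi-global identity ≥ 0.90
(short reads) or 0.80 (long reads); ties and sub-threshold hits are
uninformative. The 20-nt flank requirement each side is far beyond the
4⁻²⁰ chance-match scale; a read containing both flanks necessarily
contains the whole intervening repeat. Long reads are first narrowed to
the junction neighbourhood by locating the pilV anchor tail, keeping the
probe scan linear in read count rather than read length.

Paired-end mates are typed independently and a pair counts once; if both
mates are typed they must agree, otherwise the pair is dropped
(one junction, one vote). Platform comparison pairs per-variant ratios and
reports R² as the squared Pearson correlation; identical vectors return
exactly 1.0, and constant non-identical vectors raise (undefined
correlation) rather than returning a misleading value.

## Repeat conservation

Repeats are fixed-length recombination sites, so all comparisons are
gap-free. Per-segment-end windows (two per segment, e.g. six for a
three-segment shufflon) are the flanking repeat extended 3 nt into the
body (23-bp window over a 20-bp repeat; the registration is a convention
and is configurable); left-end
windows are reverse-complemented onto the right-end strand. The
degenerate consensus emits a base only at unanimity by default, so N marks
exactly the polymorphic positions. The minimum spanning network is a
Kruskal MST over Hamming distances plus every non-tree edge whose weight
ties the maximum edge weight on the tree path between its endpoints
(ε = 0), with label-sorted tie-breaking for determinism; the tree weight is
checked against exhaustive search over all spanning trees for ≤ 6 nodes.

## Coverage and copy number

Mean depth is averaged over **all** reference positions (absent positions
count as zero). Copy number is the plasmid/chromosome depth ratio, rounded
half-up to one decimal as genome tables print it. Paired-end classes:
a read is "proper" when its mate maps to the same replicon in FR
orientation with |insert| inside mean ± 4 SD (estimated from the data,
overridable; there is no universal criterion); wrong orientation,
cross-replicon, unmapped mate or aberrant insert is "broken". The two
classes partition primary paired coverage position by position.

## Synthetic data

The generator states one world and keeps it fixed: a 60-kb circular
single-copy plasmid; the locus at a fixed offset; 500-nt anchors; 300-nt
random segment bodies; junction repeats drawn from the 20-bp consensus
`GTGCCAATCCGGTNNGTGGA` with the two N positions drawn per junction; long
reads with lognormal lengths (mean 8 kb) and 1.5 %/9 %/4 %
substitution/insertion/deletion rates (a PacBio-subread-like default;
per-run error rates vary and are rarely reported); 2×300 bp FR pairs from
Normal(400, 40) inserts with 0.005 substitutions and no indels. Every
generator output is a pure function of the config seed (independent
numpy `SeedSequence` streams per generator); reads may wrap the circular
origin, and truth coordinates are modulo plasmid length. Quality strings
are constant (no stage consumes them).

Deliberate desk-scale choices, and what a green test does *not* establish:

- **TV criterion.** Mixture recovery is measured as total-variation
  distance between estimated ratios and the **realized** per-read truth
  frequencies, so it measures assignment error. Against the latent
  Dirichlet vector, multinomial sampling noise alone at 2,000 reads over
  48 categories contributes an expected TV ≈ 0.05, which would swamp the
  method's own error.
- **Short-read region.** For the cross-platform check, short-read inserts
  are drawn from the locus span rather than the whole plasmid: ~2,000
  desk-scale pairs stand in for the junction-covering subset of a deep
  whole-genome run (genome-wide drawing would leave ~20 informative pairs
  and the comparison would measure shot noise). Plain simulation defaults
  to the whole plasmid.
- **Repeat-window families.** With shared junction repeats drawn in one
  orientation, extracted left- and right-end windows form a forward and a
  reverse-complement family; real shufflon repeats sit in inverted
  orientation pairs such that all segment-end regions share one consensus.
  Conservation statistics on generated loci therefore show two clusters;
  the repeat operations themselves are tested on directly constructed
  fixtures.
- No chimeric reads, adapters, polymerase-read/subread structure,
  quality-aware errors, or inter-plasmid homology are modelled, so
  recovery rates here bound what identical settings achieve on real runs
  only loosely.

## Degenerate inputs and tie-breaks

Empty reads raise; reads shorter than the pilV→rci distance can never be
assigned. Zero assigned reads yields a flagged empty abundance table (the
totals are still reported). Candidate scoring iterates labels in sorted
order and breaks score ties lexicographically; the strand with the better
anchor evidence is used, forward preferred on exact ties. All
simulation-backed tests fix their seeds.
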