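# Methods

`ampmux` models and decodes the hardest common case in multiplex CRISPR
genotyping: a single consensus gRNA cutting a family of near-identical
alleles -- paralogs, homoeologous sub-genome copies, and tandem duplicates
-- read out by short consensus-primer amplicons. This note describes the
models, the numerical choices, and exactly what the synthetic world does
and does not establish.

## The locus model

A locus is a set of alleles, each with a gene name, a chromosome-copy
label, an ordinal position in that copy's tandem layout, a genomic start
offset, a sequence held at amplicon-plus-flank scale, exon intervals, and
declared tandem-repeat tracts. Coordinates are 0-based, half-open. Two
allele-level relations drive everything downstream:

* **amplicon-identical pairs** -- alleles whose consensus-primer products
  are byte-equal. No amplicon-based decoder can separate them; they are
  first-class citizens of the model because they occur in real hybrid
  genomes (the default locus carries one such cross-gene pair).
* **repeat-only pairs** -- alleles whose products differ only in the
  length of a tandem repeat tract (here an intronic GT dinucleotide run).
  These are separable in length but not in substitution space, which is
  precisely what breaks indel-calling tools.

Pair classification is computed on a repeat-collapsed center-star multiple
alignment of the amplicon window (affine scoring: match 2, mismatch -3,
gap open 10, gap extend 0.5). Repeat collapsing rewrites any run of >= 3
copies of a 1-3 bp unit to exactly 3 copies; it is idempotent, its length
change is always a multiple of the unit length, and it is applied
identically to reads and references, so repeat-length polymorphism can
never masquerade as substitutions.

## The default synthetic locus

`build_default_locus(seed)` emulates a hybrid genotype in which the Chr8
region carrying two paralogous trichome-regulator MYB genes is tandemly
duplicated on one sub-genome: eight target alleles
(MYB186m1-MYB138m1-MYB186m2-MYB138m2 on Chr8m, MYB186a-MYB138a on Chr8a,
MYB38m/MYB38a on Chr10), all carrying one byte-identical exon-2 guide site
with a blunt cut 3 bp 5' of the NGG PAM. Design facts of this world:

* ~270 bp consensus amplicon spanning the cut and an intronic GT repeat
  (8-11 units across alleles); all products lie in the declared 264-280 bp
  range.
* MYB138m1/MYB186m2 are amplicon-identical; MYB186m1/MYB186a differ only
  in GT-repeat length. Every other pair is separated by >= 3 substitutions
  among equal-length products (so dereplication at 2 mismatches cannot
  merge distinct tags) and >= 1 substitution otherwise. Error-free control
  reads therefore collapse to exactly 7 tags.
* All within-amplicon discriminating SNPs sit upstream of the cut, as in
  the real locus where they cluster in flanking introns. Consequence: a
  dropout-fusion's amplicon reads exactly like the upstream donor plus the
  junction indel, and the downstream donor goes dark (NA) -- the read-level
  signature such events actually show. Donor-pair phasing needs the longer
  PCR fragment, which spans additional per-allele SNPs outside the
  amplicon (four upstream, seven downstream) making every allele uniquely
  identifiable on both flanks of the cut.
* Cut-to-cut distances on Chr8m are 29,000 bp (186m1->138m1) and
  62,000 bp (138m1->138m2), anchoring fusion size estimates.
* `identical_pair=False` / `repeat_only_pair=False` add one disambiguating
  SNP each, producing the fully resolvable variant used for decoder
  round-trip testing. Every discriminating column is built with a fixed
  G-A-T neighborhood (ref A, alt C) so neither state can extend a repeat
  run -- collapsing must never erase a discriminating substitution.

## Edit simulation

Per line: each chromosome copy with >= 2 cut sites draws a dropout fusion
per ordered site pair (p = 0.2 each; at most one fusion is realized per
copy, chosen uniformly among successes). A fusion joins the upstream
donor's prefix through its cut to the downstream donor's suffix from its
cut, with a junction indel at probability 0.8; the downstream donor and
all intervening alleles are lost. Surviving alleles are edited
independently (p = 0.9), drawing a signed indel size from class weights
{-1: .30, -2: .28, -4: .12, +1: .12, -3: .07, -6: .03, other: .08} -- the
frameshift classes jointly 0.82, the in-frame classes 0.10, matching the
aggregate spectrum reported for this editing system. With probability 0.1
an edited allele is chimeric: its reads are a mixture (fraction uniform in
[0.1, 0.9]) of edited and unedited product, modeling regeneration
mosaicism. Deletions span the cut; insertion content is uniform random.

Reads are merged amplicon products (paired-end merging is assumed
upstream), depth 500/allele by default, i.i.d. substitution errors at
0.1%, constant Q37, random orientation. No PCR bias, no indel sequencing
errors, no sequencer-specific error profile.

`expected_calls` defines the *observable* ground truth: a fusion is
expected as NA at the downstream donor and intervening alleles and as the
junction indel at the upstream donor. A seamless fusion (no junction
indel, equal repeat lengths) is byte-identical to an intact upstream
allele within the amplicon and is expected WT -- an information-theoretic
limit, not a decoder defect; recovery tests therefore force junction
indels on.

## Read assignment: why mismatches, not edit distance

Reads are assigned to the candidate allele minimizing the **substitution
mismatch count** of an optimal alignment. Indels are deliberately free:
they are the expected editing signal, and penalizing them would push
heavily edited reads onto the wrong allele. The reported per-allele
distance is mismatches + indel bp.

This metric makes repeat-only siblings tie at zero mismatches, and the two
assignment modes differ exactly in how ties resolve:

* `repeat_normalized` (default): repeat tracts are collapsed in read and
  reference first; remaining ties go to `ambiguous`. Repeat-only siblings
  can never steal each other's reads.
* `naive`: no collapsing; ties break by model order -- the behavior of
  reference-assignment tools that treat indels as free. Reads of the
  later repeat-only sibling are absorbed by the earlier allele and surface
  as spurious indel calls of +/-2 or multiples at the repeat tract, far
  from the cut. The mode exists to reproduce and regression-test this
  artifact, not for production use.

## Pattern calling, chimeras, NA

Per assigned read, indels overlapping cut +/- 10 bp form its pattern;
reads whose mismatch fraction exceeds 1% are discarded (the AGEseq-style
allowance: substitutions are noise, indels are signal); patterns below 1%
frequency are suppressed. A read with indels only outside the window
reports its largest one -- that is how misassignment artifacts stay
visible. An allele is chimeric when the WT pattern and an edited pattern
each reach the 0.10 floor; otherwise the dominant pattern decides.

NA calling exploits the built-in control property of consensus primers:
every allele competes in the same PCR, so an unedited control decoded with
the same pipeline gives each allele's expected read share. An allele is NA
when its sample share falls below 0.05 x its control share; total depth
below 100 is an explicit no-call, never an NA call. Members of an
amplicon-identical pair have ~zero uniquely assigned reads in the control
too, so they are never spuriously NA; they decode as WT with NaN relative
abundance, honestly reflecting that the amplicon carries no information
about them.

Dereplication is single-linkage Hamming clustering (radius 2, gapless, so
different-length reads never merge), column-majority consensus, groups
< 5 reads dropped. Unique sequences seen fewer than twice are excluded
from clustering: a singleton error read lying between two tags separated
by 3 substitutions would otherwise chain them -- the collapse that
tag-assembly parameters must avoid with paralogous reads.

## Fusion phasing

A junction-spanning sequence (Sanger-grade by assumption; mismatch
tolerance 0, configurable) is aligned end-free to every allele; flank
mismatches are counted separately upstream and downstream of the cut
(excluding cut +/- 10 bp). A flank matches an allele at zero mismatches
over >= 25 covered bp. Unique 5' and 3' matches to the same allele give a
plain indel; to different layout-colinear alleles, a fusion call with the
junction indel read off the alignment to the fused template and the
dropout length taken exactly from the layout (cut-to-cut); display
rounding to the nearest kb is left to the report layer. Multiple
zero-mismatch matches are resolved as "insufficient SNP coverage" when the
covered span contains no distinguishing positions, otherwise as
conflicting evidence; both return an explicit ambiguous result. Because
flank matching counts only substitutions, repeat-length differences never
break a flank.

## Reporting

Cohorts are tidy tables (line, allele, call, indel_size). The headline
statistics follow the conservative conventions: `mutation_rate` counts
indel + chimeric sites over all sites (NA attributable to editing only via
a flag); `cleavages_per_line` is the mean count of indel/chimeric alleles
per line, excluding NA, hence a lower bound under dropouts. Frame
classification is purely arithmetic (size mod 3); whether an in-frame
allele is functionally null is an annotation question the package does
not decide.

The published per-allele table of the 30-line knockout cohort is not
redistributable; `synthetic_ko_cohort()` is a clearly labelled synthetic
stand-in constructed from the reported aggregates (mean 5.4 indel alleles
per line, the one partially edited line with 6 edited / 2 WT alleles, the
two single-Chr8-allele lines with -2 fusion junctions, 80% of lines with
>= 1 NA allele, NA concentrated on the duplicated sub-genome, ~10%
in-frame sites). Statistics computed from it reproduce those aggregates by
construction; it carries no information beyond them.

## What a green test establishes

The simulator's world is stated, not fitted: perfect primer conservation,
substitution-only sequencing noise, no PCR competition between alleles, at
most one fusion per chromosome copy, and full knowledge of the repeat
tracts. Within that world, decoding is exact on error-free reads from a
fully SNP-resolvable locus, and the repeat-normalization and fusion-phasing
properties hold exhaustively over the default locus. Real amplicon data
adds primer-site polymorphism, chimeric PCR artifacts, depth skew, and
index hopping, none of which are modeled; green tests here establish
correctness of the algorithms, not performance on any particular MiSeq
run.
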