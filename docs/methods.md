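# Methods

This note documents the models, conventions and numerical choices
behind `msapseq`, in the order the pipeline runs.

## In-silico MSAP digestion (`msapseq.digest`)

Methylation is modelled **per CCGG site** with six states: unmethylated
(NONE), internal-cytosine methylation CmCGG (hemi or full),
external-cytosine methylation mCCGG (hemi or full), and double
methylation mCmCGG.  The cleavage table is: MspI cuts NONE,
HEMI_INTERNAL and FULL_INTERNAL; HpaII cuts NONE and HEMI_EXTERNAL;
neither cuts FULL_EXTERNAL or DOUBLE; EcoRI is treated as
methylation-insensitive.  Site-level states are sufficient to express
these rules; per-strand base maps would add nothing the enzymes can
distinguish here.

Coordinates are 0-based, half-open.  Cuts are placed after offset +1
of each motif (G^AATTC, C^CGG).  N bases break motifs — no cut is
ever inferred through ambiguity.  Fragments are maximal intervals
between consecutive cuts; sequence termini are labelled TERMINUS and
never amplify.

**Selective amplification.** Only fragments with exactly one EcoRI end
and one HpaII/MspI end are detectable: in the modelled chemistry only
the EcoRI primers carry dyes, so EcoRI–EcoRI and HH–HH products are
invisible.  The selective-base convention is fixed as follows and used
consistently everywhere (tests, generator, pipeline): with the EcoRI
cut on the left, the three bases after the AATTC remnant must equal the
EcoRI selective triplet; with the CCGG cut on the right, the four
top-strand bases immediately before the terminal C must equal the
HpaII/MspI selective tetramer; the mirror-orientation ends are compared
through the reverse complement.  Observed size is fragment length plus
a constant adaptor/primer offset (default 0, configurable — real
instruments add adaptor mass, but no published arithmetic is assumed).
The detectable window defaults to 50–500 bp, the span of a standard
500-size ladder.

## Landscape similarity (`msapseq.landscape`)

Band sizes are binned by integer floor division (default bin width
1 bp); MspI- and HpaII-channel bands are separate columns of one
matrix, so the two digestion channels are combined per sample.  The
Nei–Li/Dice coefficient `S = 2a/(2a+b+c)` ignores shared absences; a
pair with no bands at all has undefined similarity and raises.  The
percent-polymorphic conversion `p = 100·2(1−S)/(2−S)` is the exact
algebraic inversion of the Dice coefficient onto `(b+c)/(a+b+c)`; the
test suite verifies it against direct counting on random binary rows to
10 significant digits.

UPGMA is implemented directly (arithmetic-mean linkage) rather than
through a library call because two details are pinned down here and
cross-checked in tests against both scipy's average linkage and a naive
agglomeration oracle: ties are broken by the lexicographically smallest
pair of cluster labels (a cluster is labelled by its smallest leaf),
and branch lengths are half merge-height differences, so the output is
ultrametric by construction.  Distance is `1 − S`.

Reported similarity/percent values are rounded half-away-from-zero at
the printed precision (4 decimals for S, 2 for percents), with a
12-decimal guard so a decimal half-point reached through float
arithmetic still rounds upward.

**Polymorphism accounting.** A band is *gained* in a pair when every
somaclone replicate carries it and no standard replicate does, *lost*
in the reverse case; replicate-inconsistent bands are ignored.  This
unanimity rule is a deliberate choice: the analysis targets *repeated*
polymorphisms, and a band that flickers across the four replicate
individuals of a variant is evidence of scoring noise, not of a stable
change.  A band gained-or-lost in both pairs is scoped
WITHIN_BOTH_PAIRS (direction agreement is tracked as
gained/lost/mixed), otherwise WITHIN_ONE_PAIR; each polymorphic band
lands in exactly one scope, so totals add.

## Sequencing design (`msapseq.design`)

Capacity is the plain product `mean_len × amplicons_per_combo ×
n_samples × coverage × n_combos`, with utilisation against a per-run
device capacity (default 35 Mnt, a 454 GS Junior run).  Combination
selection makes every combination carrying a both-pairs polymorphism
mandatory and fills remaining slots by descending polymorphic-band
total in the HpaII channel, ties broken by combination label order.
Ranking on the HpaII channel is intentional: HpaII digestion is the
polymorphism-rich readout (CG methylation changes dominate), and the
HpaII totals are what separates otherwise similar combinations.

## Synthetic studies (`msapseq.simulate`)

The generator emulates the targeted experimental design: two unrelated
cultivar genomes; four replicate individuals per variant; nine primer
combinations; amplicon sizes drawn uniquely per genome from 60–340 bp
(mean ≈ 200 bp, matching the planning assumption); 10× per-amplicon
read coverage; substitution read errors at 0.005/nt by default
(454-like); MID barcodes for the four pooled samples.

Genomes are assembled from random motif-free spacers and explicit
**amplicon cassettes** `GAATTC + e_sel + insert + h_sel + CCGG`, one
controllable CCGG per cassette.  After assembly the sequence is
scrubbed so that no unplanted motif and no selective-matching context
survives anywhere else; predicted spectra are therefore exactly the
cleavable cassette bands, which makes every planted methylation flip's
expected band change recomputable through the digestion engine (and
the truth set is stored that way).  Background CCGG states are drawn
from a configurable distribution, default 60% NONE / 25% FULL_INTERNAL
/ 10% FULL_EXTERNAL / 5% DOUBLE — real wheat proportions are unknown;
this mix is documented as arbitrary.

Planted somaclone changes are state flips at cassette CCGGs.  Because
the two digestion channels of a sample are pooled into one sequencing
library and a fragment has the same sequence in both channels, a flip
that silences only one channel (e.g. NONE→FULL_INTERNAL) changes MSAP
bands but is invisible at the read level.  Default planted flips
therefore cross the pooled presence/absence divide (e.g. NONE→DOUBLE,
FULL_EXTERNAL→NONE); channel-asymmetric flips remain expressible
through the API and are unit-tested at the digest level.  *Shared*
changes are planted as byte-identical cassettes in both genomes (these
are pre-sanitised and protected from scrubbing) with the identical
flip applied in both pairs, so their amplicons are the ground-truth
consensual set.  Only sequence-free methylation changes are planted:
the differences under study are epigenetic, and a SNP model would
confound the differential-contig readout.  Reads are full-length
amplicons in random orientation with i.i.d. substitutions (barcode
included) at constant Q30; homopolymer indels, chimeras and PCR
duplicates are not modelled.

**What passing tests show — and don't.**  The synthetic study
validates the machinery: band bookkeeping, demultiplexing, clustering,
alignment statistics and the reciprocal differential logic, at a scale
of ~100 bands rather than ~2000.  Within-variant replicates are
identical (no scoring noise model), so synthetic within-variant
similarity is exactly 1 and between-variant similarity (~0.89 at the
default 36 cassettes / 6 flips) is far below the ~0.99 of a real
2000-band panel where each change weighs ~0.05%.  Real-data hazards
deliberately out of scope: electropherogram peak calling, partial
digestion, 454 homopolymer errors, and comigration of unrelated
fragments of equal size (the generator gives every cassette of a
genome a unique size so planted truths are unambiguous).

## Read analysis (`msapseq.contigs`)

Demultiplexing matches the MID barcode against the read prefix within
a mismatch budget (default 0; ambiguous or non-matching reads stay
unassigned) and strips it.  Adaptor trimming removes the longest
prefix/suffix adaptor at ≤1 substitution; reads shorter than 40 nt
after trimming, or with mean Phred quality below 20, are discarded.

Assembly is replaced by **greedy centroid clustering**: reads sorted by
descending length then id; each read joins the first centroid reached
at ≥97% global (Needleman–Wunsch, edlib) identity, forward or
reverse-complement, else founds a centroid; consensus is the
per-column majority over the orientation-normalised members of the
dominant length class; clusters with fewer than 2 reads are dropped.
For non-overlapping amplicon pools this is equivalent to assembly and,
unlike a GUI assembler, fully specified.

Contig comparison uses Smith–Waterman local alignment (Biopython's
PairwiseAligner; match +1, mismatch −2, first gap column −5, each
further gap column −2, both strands) with a Karlin–Altschul e-value
`E = K·m·n·e^(−λ·score)`.  λ is solved numerically from
`Σ pᵢpⱼ e^(λ sᵢⱼ) = 1` at uniform base composition (λ ≈ 1.33 for the
default scores); K defaults to 0.3 and is configurable rather than
computed by the full lattice-sum algorithm — at these score scales the
1e-5 threshold decision is insensitive to K across orders of
magnitude (a perfect 60-mer scores 60, giving E ~ 1e-29·K·m·n, while
the best random local match scores ~10–15, giving E ≫ 1).  `m·n` uses
the summed subject-pool length (database search semantics).

A contig is *differential* when its best hit in the paired pool has
`e > 1e-5`; the *consensual* set keeps pair-1 differential contigs
with any hit at `e ≤ 1e-5` among pair-2's differential contigs.
Any-hit (not reciprocal-best) matching is used, and gain/loss
direction agreement between the pairs is reported as metadata but not
enforced — both choices are flagged to users because a stricter
reciprocal or direction-consistent rule is equally defensible.

## Determinism and problem sizes

Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; reruns are byte-identical including FASTQ
output.  The read-analysis stages use no randomness at all.  Test
problem sizes — 36-cassette genomes (~20 kb), 20 recovery replicates,
100 oracle genomes ≤ 2 kb, alignment oracle pairs ≤ 50 nt — were
chosen as the smallest scales at which every failure mode the suite
targets (masked bands, cluster splits, spurious alignment hits) can
actually occur.

## Known limitations

- Site-level methylation states cannot express strand-asymmetric
  patterns beyond hemi/full labels.
- The selective-base orientation and amplicon-size arithmetic are
  conventions (documented above), not measured instrument behaviour.
- Greedy clustering order can split borderline clusters near the
  identity threshold; with ≥10× coverage and <1% error this does not
  occur in practice.
- The e-value is ungapped theory applied to gapped scores with a fixed
  K; it is a filter, not a calibrated significance estimate.
- Within-variant replicate noise is not modelled, so the synthetic
  polymorphism accounting never exercises the
  replicate-inconsistency branch outside unit tests.
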