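# msapseq

Tools for combining **methylation-sensitive amplified polymorphism
(MSAP)** fingerprinting with **pooled deep amplicon sequencing** to find
genomic regions whose DNA methylation changes *repeatedly* — for example
in somaclones regenerated from plant tissue culture, compared against
their source cultivars.

The package is aimed at plant epigenetics groups who use the
HpaII/MspI isoschizomer pair to read CCGG methylation as band
presence/absence, and who want to (i) quantify how similar two
methylation landscapes are, (ii) plan how many primer combinations fit
a sequencer run, and (iii) pull out the amplicons that differ between
standard and somaclone in **two independent cultivar pairs at once** —
the strongest candidates for methylation changes that recur under
in vitro cultivation.  Because real somaclone panels are rarely
available for method development, a first-class synthetic-data module
generates cultivar genomes, methylomes, planted methylation changes and
error-bearing pooled reads with a machine-readable truth set, so the
whole pipeline is testable end to end.

## The method

**MSAP digestion.** Genomic DNA is double-digested with EcoRI
(G^AATTC) plus one of the isoschizomers MspI or HpaII (both C^CGG),
which differ in methylation sensitivity at the CCGG site:

| CCGG state            | MspI | HpaII |
|-----------------------|------|-------|
| unmethylated          | cut  | cut   |
| hemi/full CmCGG       | cut  | —     |
| hemi mCCGG            | —    | cut   |
| full mCCGG, mCmCGG    | —    | —     |

Fragments with one EcoRI and one HpaII/MspI end that match the
selective primer extensions (three EcoRI-side bases, four
HpaII/MspI-side bases; nine combinations I–IX) become detectable bands
in a 50–500 bp window.  Comparing the MspI and HpaII channels of the
same sample reads out the methylation state of each site.

**Landscape similarity.** Band spectra are binned into a binary
presence/absence matrix.  For two samples with `a` shared bands and
`b`, `c` private bands, the Nei–Li/Dice similarity is

    S = 2a / (2a + b + c)

and the implied percentage of polymorphic amplicons is
`p = 100 · 2(1−S)/(2−S)`.  Samples are clustered with UPGMA
(arithmetic-mean linkage, ultrametric dendrogram, Newick output).

**Sequencing design.** Required capacity is
`mean length × amplicons per combination × samples × coverage ×
combinations`; primer combinations whose polymorphic bands recur in
*both* cultivar pairs are mandatory for sequencing, remaining slots are
filled by polymorphism yield.

**Differential contigs.** Pooled reads are demultiplexed by MID
barcode, quality-filtered, and clustered per pool by greedy centroid
clustering (97% global identity, reverse-complement aware); contigs
supported by fewer than two reads are discarded.  Each pool's contigs
are searched against the paired pool by Smith–Waterman local alignment
with a Karlin–Altschul e-value; contigs with no hit at `e ≤ 1e-5` are
*differential*.  Differential contigs of pair 1 that match a
differential contig of pair 2 form the *consensual* set — the
repeatedly polymorphic amplicons.

## Worked example

Run the whole pipeline on a synthetic two-pair study (two cultivar
genomes, 6 planted methylation flips per pair of which 3 sit in
cassettes shared between the pairs, error-free reads at 10× coverage):

```bash
msapseq run-all --seed 7 --outdir run7
```

Headline numbers from `run7/summary.json`:

```json
{
  "n_bands": 103,
  "mean_similarity_between_variant": 0.8891,
  "percent_polymorphic_between": 19.97,
  "polymorphic_within_both_pairs": 6,
  "selected_combinations": ["I", "II", "III", "VI", "VII", "VIII"],
  "capacity_total_nt": 14400000,
  "n_reads": 920,
  "contigs_per_pool": {"1": 19, "2": 17, "3": 28, "4": 28},
  "differential_counts": {
    "pair1_standard_only": 4, "pair1_somaclone_only": 2,
    "pair2_standard_only": 3, "pair2_somaclone_only": 3
  },
  "n_consensual": 3,
  "n_truth_shared": 3,
  "consensual_matches_truth": true
}
```

Reading this: the 16 simulated MSAP samples produced 103 distinct
bands; standard vs somaclone landscapes are 0.8891 similar (19.97%
polymorphic bands — the synthetic study is far smaller than a real
2000-band MSAP panel, so each planted change weighs more); 6 band-level
polymorphisms recur in both pairs (3 planted shared flips × 2
digestion channels), which forces their primer combinations into the
six selected for sequencing; 920 pooled reads demultiplex cleanly and
cluster back into exactly the amplicons of each pool; the four
directional difference sets intersect to 3 consensual contigs, which
match the 3 planted shared methylation changes exactly
(`consensual_matches_truth`).

Every stage is also available as a separate subcommand (`simulate`,
`digest`, `matrix`, `similarity`, `tree`, `account`, `select-combos`,
`capacity`, `demux`, `trim`, `cluster`, `diff`, `consensual`) operating
on plain FASTA/FASTQ/TSV/CSV/Newick files, and as library functions
(`msapseq.digest`, `.landscape`, `.design`, `.contigs`, `.simulate`).

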