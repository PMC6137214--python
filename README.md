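# emastkit

Discovery of candidate **EMAST** loci in animal genomes, and calling of
tumor/normal microsatellite instability at the discovered markers.

EMAST (Elevated Microsatellite Alterations at Selected Tetranucleotide
repeats) is a form of microsatellite instability — insertions or
deletions of whole repeat units at particular tetranucleotide
microsatellites — seen in colorectal and several other cancers and
associated with MSH3 mismatch-repair dysfunction. Studying it in animal
models requires a species-specific marker panel, but which of the many
thousands of tetranucleotide repeats in a genome are *susceptible* to
instability? `emastkit` implements a discovery pipeline built on the
observation that unstable human loci carry characteristic sequence
motifs in their immediate flanking DNA, plus the downstream calling
rules for scoring a panel in tumor/normal pairs. It is aimed at cancer
researchers building EMAST/MSI marker panels for model organisms.

## Method

For a repeat unit *u* (default CTTT, i.e. AAAG on the opposite strand)
and genome *S*:

1. **Repeat scan.** Find every maximal perfect tandem repeat
   *u*ⁿ with *n* ≥ 10 (complete units only, one strand, optional
   reverse-complement scan). Coordinates are 0-based half-open.
2. **Flank model.** From a panel of known unstable loci, learn two
   11-column position weight matrices (PWMs) — one per flank — with a
   ZOOPS ("zero or one occurrence per sequence") EM motif search over
   the 25-nt flanking sequences, against a 0-order background estimated
   from those flanks. A window *w* scores
   `score(w) = Σⱼ log₂( p(wⱼ, j) / b(wⱼ) )` bits.
3. **Motif filter.** A locus survives only if *both* flanks contain a
   window scoring at or above the model threshold (default: the minimum
   score among accepted training sites).
4. **Similarity and ranking.** Each surviving locus (flank + tract +
   flank region) is globally aligned (match +1, mismatch −1, gap −2,
   end gaps penalised) against every known locus; percent similarity is
   matched columns over alignment length. Candidates are
   percentile-ranked by combined PWM score (average ranks for ties) and
   the final panel keeps loci ≥ 85% similar with ≥ 13 repeat units.
5. **Instability calling.** Given repeat-unit counts per marker ×
   mouse × tissue: a marker shows *normal-tissue instability* when any
   normal count deviates from the published reference count; a tumor
   shows *EMAST* at a marker when its count differs from the matched
   normal of the same mouse; a tumor is *EMAST-positive* with ≥ 1
   unstable marker. Unit-count differences correspond to alignment gaps
   of 4 (or multiples of 4) nucleotides; any other tract-length
   difference is rejected as a non-unit indel.

All inputs can also be simulated (`emastkit.synthetic`): genomes with
planted repeats and flank motifs, flank training sets with a chosen
motif occurrence, and count tables with planted instability — each with
an exact ground-truth record.

## Worked example

```bash
python examples/call_instability.py
```

```
panel markers:               7
  EMAST (tumor vs normal):   5
  normal-tissue instability: 5
  both:                      4
  any instability:           6
EMAST-positive mice:         ['1', '2', '4', '5', '6', '7']
controls with instability:   0 of 2
```

The packaged count table covers seven discovered CTTT markers and two
control ATCT markers across seven tumor-bearing mice. Five markers show
EMAST (tumor ≠ matched normal in at least one mouse), five show
instability already in macroscopically normal tissue, four show both
and six show either — while the two control markers, picked without the
motif criterion, are completely stable. That contrast is the point of
the pipeline: motif-selected repeats are the ones that destabilise.

The other examples demonstrate the upstream stages: `scan_repeats.py`
(repeat scan and length spectrum), `discover_flank_motifs.py` (ZOOPS-EM
recovery of a motif planted in 6 of 7 flanks), and `rank_candidates.py`
(the full chain on a synthetic genome — 20 planted tracts, of which
exactly the 8 motif-bearing ones survive filtering and selection).

There is also a thin CLI:

```bash
emastkit scan genome.fa -o loci.bed
emastkit discover panel.tsv --seed 3 -o model
emastkit pipeline genome.fa model.json panel.tsv -o candidates.tsv
emastkit call counts.tsv -o calls
```

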