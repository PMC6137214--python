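# Methods

This note records the models, conventions and numerical choices behind
`emastkit`, and what the synthetic data used in the tests does and does
not establish about real genomes.

## Repeat scanning

A tandem-repeat locus is a **maximal perfect run of complete unit
copies**: `[start, end)` with `end − start = k·n` for unit length `k`,
the subsequence equal to the unit repeated `n` times, and neither the
`k` bases before `start` nor after `end` equal to the unit. Three
conventions follow from how repeat counts are used downstream:

* **Complete units only.** Count tables report integer unit numbers, so
  a trailing partial unit (the final `C` of `CTTTCTTTC`) is not part of
  the locus. When two sequences of the same locus are compared
  (`repeat_count_delta`), the tract length *in nucleotides* — including
  any partial trailing unit — is still measured, so that an indel that
  is not a whole number of units (e.g. 3 nt in a tetranucleotide tract)
  is detected and rejected rather than silently rounded.
* **Perfect repeats.** One mismatching base (including N, which never
  matches) ends a run. No interruption tolerance is offered; tolerant
  scanning would change the meaning of the unit count.
* **One rotation, one strand.** The unit is matched verbatim; `TTTC` is
  the same biological tract as `CTTT` in another register and would
  duplicate loci if also reported. The reverse-complement scan reports
  minus-strand loci (e.g. `AAAG` runs when querying `CTTT`) in forward
  coordinates with strand `−`; their flanks are returned in locus
  orientation.
* The unit itself must be aperiodic — `AAAA` or `ATAT` are rejected so
  a tetranucleotide query cannot silently degenerate to a shorter
  repeat class. Units of length 3 are accepted alongside length 4,
  since trinucleotide repeats can show the same instability.

Defaults: minimum 10 units for genome scans, 25-nt flanks. These are
the characteristics of the known unstable loci the pipeline is modelled
on (all ≥ 10 units; flank effects are attributed to the immediate
25 nt).

The scanner is validated against an exhaustive every-offset oracle on
random sequences salted with planted runs, plus maximality,
non-overlap and determinism properties.

## Flank motif model

**PWM.** 4 × 11 base-probability matrix; estimation from `s` aligned
sites uses background-scaled pseudocounts:
`p(b,j) = (c(b,j) + α·g(b)) / (s + α)` with pseudocount `α = 0.25`
(Laplace scaled by the background `g`). Scores are summed per-column
log-odds in bits; an `N` in a scanned window contributes 0 for its
column (no evidence either way). With `α = 0` unobserved bases get
probability 0 and score −∞; discovery and scanning always use a
positive pseudocount. Window scanning returns the smallest offset among
windows within 10⁻⁹ bits of the maximum — exact ties between distinct
windows do occur, and without the tolerance the tie rule would depend
on floating-point summation order.

**Background.** 0-order base frequencies estimated from the training
flanks themselves (with a small floor so log-odds stay finite). The
flanks of unstable tetranucleotide loci are repetitive and C/T-rich; a
genome-wide background would systematically inflate their scores.

**Discovery (ZOOPS-EM).** The flanking motif is present in most but
not all training flanks, so the model allows zero or one occurrence per
sequence with occurrence probability γ (re-estimated each iteration).
EM runs from each of `n_starts` (default 50) seed words — enumerated
11-mers ranked by surprisal under the background, ties ordered by a
seeded permutation so runs are reproducible — with the seed word given
probability 0.7 in its column. Iteration stops when the objective
improves by < 10⁻⁶ or after 200 iterations; the best final objective
wins. Because the M-step uses Dirichlet pseudocounts, the quantity
guaranteed non-decreasing (and returned as the iteration trace) is the
penalized log-likelihood — data log-likelihood plus the Dirichlet prior
term. Accepted sites are sequences whose best-window posterior reaches
0.5; the model threshold defaults to the minimum log-odds score among
accepted training sites, so the filter reproduces "found in most
training flanks"-style acceptance without any hand-set cutoff.

**E-value.** Approximated as (number of enumerated seed words) × the
one-sided normal tail probability of the final information content
under a background null, with per-column moments from the χ²
approximation to multinomial sampling error. It is a rough significance
guide for comparing runs on similar-sized inputs; it is **not**
comparable with E-values from other motif-discovery software, whose
null models and corrections differ.

**Known limitation.** EM occasionally converges to a one-position
phase shift of a planted motif when the shifted register happens to
score slightly higher on the realised data; over 20 seeded replicates
of the standard recovery fixture (motif in 6 of 7 flanks, one mutation
per site) the planted consensus is recovered within Hamming distance 1
in 90–100% of runs depending on the seed batch.

Motif discovery is trained per repeat-unit category; mixing units in
one panel is an error, since flank composition differs by unit type.
Discovery on a panel without a real shared motif converges to a
low-information matrix with a large E-value — the attempt is allowed
and reported honestly rather than refused.

## Candidate pipeline

* A locus passes the filter only if **both** flanks score at or above
  their thresholds; the combined score is the sum of the two best
  window scores (the simplest composable statistic over two
  independent flanks). Loci with contig-edge-truncated flanks cannot
  be checked on both sides and are excluded by default.
* **Percent similarity** is global-alignment column identity over the
  flank + tract + flank region: Needleman–Wunsch with match +1,
  mismatch −1, gap −2, end gaps penalised, traceback preferring
  diagonal, then up, then left (fully deterministic);
  `similarity = 100 · matches / alignment_length`. Alignment rather
  than Hamming distance is required because regions differ in tract
  length; the scoring constants are fixed so results are reproducible
  bit-for-bit.
* **Percentile rank**: `100 · rank / n` with average ranks for ties.
  `top_decile` flags scores *strictly above* the 90th percentile —
  "within the top tenth percentile" is read as the open upper decile,
  which also keeps exactly one of ten distinct scores flagged.
* **Selection**: similarity ≥ 85% and ≥ 13 units, sorted by (contig,
  start). Candidate names follow the `C{chrom}R{n_units}` convention
  with `.2`, `.3`… suffixes on collision.

## Instability calling

* *Normal-tissue instability*: any present normal count differs from
  the published reference count. An alternative definition — normal
  counts differ across mice — is available (`across_mice`); the two
  agree on every marker of the packaged table, and the default is the
  reference-count comparison because it also covers the case where all
  mice deviate identically.
* *EMAST per marker*: the set of mice with both counts present and
  tumor ≠ normal. Missing cells are represented explicitly and
  skipped — never imputed, never called. A marker with no comparable
  pair is an error, not a silent negative.
* *EMAST-positive tumor*: ≥ `min_unstable_markers` (default 1) panel
  markers unstable in that mouse; control markers not identified by
  the discovery algorithm are excluded from the panel by default.

The packaged `table1.tsv` transcribes the reference study's count
table: seven discovered CTTT markers, two ATCT controls, seven
tumor-bearing mice, and seven parental-strain colon samples for the
C10R18 marker. One marker (C19R16) lists only six normal values for
seven mice; the missing cell is left blank (assigned to sample 7 —
every printed value equals the published count, so no call depends on
which sample is missing). Applying the ≥ 1-unstable-marker rule to
this table marks six of the seven mice EMAST-positive.

## Synthetic data

The generators are pure functions of their arguments including the
seed. The genome generator draws i.i.d. background bases, writes each
planted tract, embeds exact consensus motifs inside the flanks of
motif-bearing plants (offsets keep the unit-length bases nearest the
tract free), sets guard bases so no tract extends beyond its planted
length, and re-scans the result to verify the planted truth is exactly
what a scan reports. Plants are separated by at least flank length +
motif width so truths never collide.

What this emulates: repeat tracts of realistic unit counts (10–25),
motif-bearing vs motif-free flanks, count tables with unit-sized shifts
(±1, ±2) at controlled rates around published counts of 14–18 — the
regimes the calling rules operate in. What it does not emulate: GC
isochores and repeat families, interrupted/imperfect repeats,
sequencing error, or the flank-sequence homology structure of real
genomes. Passing tests therefore demonstrate algorithmic correctness
on the defined model, not discovery performance on a real genome;
genome-scale runs require only a FASTA file and the same entry points.

Problem sizes used in the tests and the acceptance script: 100 random
sequences of 2–12 kb for scanner/oracle equivalence, 20-kb two-contig
genomes with 20 plants for the pipeline, 20 replicates for motif
recovery, 1,000 random PWM/flank pairs for scan checks, 50 random
pairs for alignment checks, and 500 simulated mice × 5 markers for
caller rate recovery — sizes at which every oracle is exhaustive and
the binomial check is tight (99% CI half-width ≈ 0.05 at p = 0.3).

## Committed fixtures

`tests/data/` holds a deterministic snapshot generated by
`scripts/make_fixtures.py`: a two-contig genome with 20 planted CTTT
tracts (8 motif-bearing), its truth BED, and a 9-locus known-locus
panel whose entries are diverged copies (2 substitutions per flank,
±1 unit) of the motif-bearing plants plus one motif-free entry. The
panel is synthetic — a structural stand-in for a published human locus
panel, whose sequences are not shipped here — and is labelled as such.
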