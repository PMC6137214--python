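"""Scan a genome for CTTT tandem repeats and tabulate the length spectrum.

Builds a small synthetic genome with planted repeat tracts, scans both
strands, and prints each locus plus the per-contig abundance of repeat
lengths — the same summary used to compare repeat-length distributions
between species.
"""

from emastkit.repeats import RepeatUnit, repeat_length_spectrum, scan_genome
from emastkit.synthetic import PlantSpec, generate_genome

unit = RepeatUnit("CTTT")
plants = [PlantSpec(unit, n, with_motifs=False) for n in (10, 12, 12, 15, 18)]
records, truth = generate_genome(
    length=30_000, plants=plants, motif_5p="GACTGTCCAGT", motif_3p="CAGTGGATCGA", seed=5
)

loci = scan_genome(records, unit, min_units=10, scan_reverse=True)
print(f"{len(loci)} maximal (CTTT)n loci with n >= 10:")
for loc in loci:
    print(f"  {loc.chrom}:{loc.start}-{loc.end}  n_units={loc.n_units}  strand={loc.strand}")

print("\nRepeat-length spectrum (contig, n_units) -> count:")
for key, count in sorted(repeat_length_spectrum(records, unit).items(), key=str):
    print(f"  {key}: {count}")

# Each line is one perfect repeat tract in 0-based half-open coordinates;
# the spectrum counts how many tracts of each exact unit number exist per
# contig (longer tracts are rarer, as in real genomes).
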