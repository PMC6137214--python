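"""Regenerate the committed synthetic test fixtures (deterministic).

Produces, under tests/data/:

* synthetic_genome.fa    — two ~20-kb contigs with 20 planted CTTT
                           tracts (10-18 units); 8 carry the flank
                           motifs, 12 do not
* synthetic_truth.bed    — planted-locus truth (name = unit_nunits_motif)
* synthetic_known_panel.tsv — a 9-locus known-locus panel; 8 loci are
                           slightly diverged copies (2 substitutions
                           per flank, +/-1 repeat unit) of the planted
                           motif-bearing genome loci, so their flanks
                           carry the motifs in 8 of 9 sequences; the
                           9th is motif-free random sequence.  A
                           synthetic stand-in for a published panel.

Run from the repository root: python scripts/make_fixtures.py
"""

from pathlib import Path

import numpy as np

from emastkit.io import KnownLocusRecord, write_fasta, write_known_loci
from emastkit.repeats import RepeatUnit, extract_flanks, scan_genome
from emastkit.synthetic import PlantSpec, generate_genome

OUT = Path(__file__).resolve().parent.parent / "tests" / "data"

MOTIF_5P = "GACTGTCCAGT"
MOTIF_3P = "CAGTGGATCGA"
UNIT = RepeatUnit("CTTT")
GENOME_SEED = 20180913
PANEL_SEED = 41


def make_genome() -> tuple:
    n_units = [13, 14, 15, 16, 17, 18, 13, 15, 10, 11, 12, 13, 14, 15, 16, 17, 10, 11, 12, 18]
    plants = [
        PlantSpec(UNIT, n, with_motifs=(i < 8), contig="chr1" if i % 2 == 0 else "chr2")
        for i, n in enumerate(n_units)
    ]
    records, truth = generate_genome(
        length=20000, plants=plants, motif_5p=MOTIF_5P, motif_3p=MOTIF_3P,
        seed=GENOME_SEED, verify=True,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta(records, OUT / "synthetic_genome.fa")
    with open(OUT / "synthetic_truth.bed", "w", newline="\n") as fh:
        for t in sorted(truth.loci, key=lambda t: (t["contig"], t["start"])):
            name = f"{t['unit']}_{t['n_units']}_{'motif' if t['with_motifs'] else 'plain'}"
            fh.write(f"{t['contig']}\t{t['start']}\t{t['end']}\t{name}\t0\t+\n")
    return records, truth


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for j in rng.choice(len(out), size=n_subs, replace=False):
        out[j] = [b for b in "ACGT" if b != out[j]][rng.integers(3)]
    return "".join(out)


def make_panel(records, truth) -> None:
    """Panel of diverged copies of 6 motif-bearing genome loci + 1 random."""
    rng = np.random.default_rng(PANEL_SEED)
    by_id = {r.id: r for r in records}
    motif_truth = [t for t in truth.loci if t["with_motifs"]]
    loci = scan_genome(records, UNIT, 10)
    by_pos = {(l.chrom, l.start): l for l in loci}
    panel = []
    for i, t in enumerate(motif_truth):
        fl = extract_flanks(by_pos[(t["contig"], t["start"])], by_id[t["contig"]])
        n_units = t["n_units"] + int(rng.integers(-1, 2))
        panel.append(
            KnownLocusRecord(
                locus_id=f"H{i + 1}R{n_units}", unit=UNIT.bases, n_units=n_units,
                upstream_flank=_mutate(fl.upstream_flank, 2, rng),
                downstream_flank=_mutate(fl.downstream_flank, 2, rng),
            )
        )
    random_flanks = "".join(rng.choice(list("ACGT"), size=50))
    panel.append(
        KnownLocusRecord(
            locus_id=f"H{len(panel) + 1}R14", unit=UNIT.bases, n_units=14,
            upstream_flank=random_flanks[:25], downstream_flank=random_flanks[25:],
        )
    )
    write_known_loci(panel, OUT / "synthetic_known_panel.tsv")


if __name__ == "__main__":
    records, truth = make_genome()
    make_panel(records, truth)
    print(f"fixtures written to {OUT}")
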