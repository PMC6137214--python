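from pathlib import Path

import pytest

from emastkit.io import read_fasta, read_known_loci
from emastkit.motifs import train_motif_model

DATA = Path(__file__).parent / "data"

# Motifs planted in the committed fixtures (see scripts/make_fixtures.py)
FIXTURE_MOTIF_5P = "GACTGTCCAGT"
FIXTURE_MOTIF_3P = "CAGTGGATCGA"


@pytest.fixture(scope="session")
def fixture_genome():
    return read_fasta(DATA / "synthetic_genome.fa")


@pytest.fixture(scope="session")
def fixture_truth():
    """Planted-locus truth: list of (chrom, start, end, n_units, with_motifs)."""
    rows = []
    for line in (DATA / "synthetic_truth.bed").read_text().splitlines():
        chrom, start, end, name, _score, _strand = line.split("\t")
        unit, n_units, flag = name.split("_")
        rows.append((chrom, int(start), int(end), int(n_units), flag == "motif"))
    return rows


@pytest.fixture(scope="session")
def known_panel():
    return read_known_loci(DATA / "synthetic_known_panel.tsv")


@pytest.fixture(scope="session")
def trained_model(known_panel):
    return train_motif_model(known_panel, seed=3)
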