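"""Reading and writing the file formats the pipeline touches.

FASTA (plain or gzipped) for genomes, TSV for known-locus panels and
annotation tables, BED6 for genome-browser interval output.  All
coordinates written here are 0-based half-open (BED convention); the
candidate TSV additionally carries 1-based inclusive columns for human
reading.  Everything is UTF-8 text with LF line endings.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "KnownLocusRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_known_loci",
    "write_known_loci",
    "write_candidates",
    "write_loci",
]

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the record and offset."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase.

    Lowercase (soft-masked) input is uppercased on construction; any
    other character is rejected.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise FastaParseError(
                f"record {self.id!r}: illegal character {seq[offset]!r} at offset {offset}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KnownLocusRecord:
    """A reference repeat locus: unit, copy number and 25-nt flanks."""

    locus_id: str
    unit: str
    n_units: int
    upstream_flank: str
    downstream_flank: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"{self.locus_id}: n_units must be >= 1")
        object.__setattr__(self, "unit", self.unit.upper())
        object.__setattr__(self, "upstream_flank", self.upstream_flank.upper())
        object.__setattr__(self, "downstream_flank", self.downstream_flank.upper())

    @property
    def region(self) -> str:
        """upstream flank + repeat tract + downstream flank."""
        return self.upstream_flank + self.unit * self.n_units + self.downstream_flank


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently handling gzip (detected by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    One record per header, order preserved; soft-masked lowercase is
    uppercased.  An empty file yields an empty list.  Characters outside
    {A,C,G,T,N} or a file that does not start with '>' raise
    :class:`FastaParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_maybe_gzip(path) as handle:
        text = handle.read()
    if not text.strip():
        return []
    if not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: malformed FASTA, first record has no '>' header")
    records = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA (LF endings)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


_KNOWN_COLUMNS = ["locus_id", "unit", "n_units", "upstream_flank", "downstream_flank"]


def read_known_loci(path: str | Path, flank_len: int = 25) -> list[KnownLocusRecord]:
    """Read a known-locus panel TSV (locus_id, unit, n_units, flanks).

    Flanks shorter than ``flank_len`` are accepted but flagged truncated.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _KNOWN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        up, down = str(row.upstream_flank), str(row.downstream_flank)
        out.append(
            KnownLocusRecord(
                locus_id=str(row.locus_id),
                unit=str(row.unit),
                n_units=int(row.n_units),
                upstream_flank=up,
                downstream_flank=down,
                truncated=(len(up) != flank_len or len(down) != flank_len),
            )
        )
    return out


def write_known_loci(records: Iterable[KnownLocusRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_KNOWN_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.locus_id}\t{r.unit}\t{r.n_units}\t{r.upstream_flank}\t{r.downstream_flank}\n"
            )


# BED score column is an integer 0-1000; combined log-odds scores (bits)
# are mapped linearly at 20 per bit and clamped.
_BED_SCORE_PER_BIT = 20.0


def _bed_score(bits: float) -> int:
    return int(round(min(1000.0, max(0.0, bits * _BED_SCORE_PER_BIT))))


_CANDIDATE_TSV_COLUMNS = [
    "locus_id",
    "contig",
    "start",
    "end",
    "start_1based",
    "end_1based",
    "strand",
    "unit",
    "n_units",
    "score_5p",
    "score_3p",
    "combined_score",
    "best_similarity_pct",
    "best_similarity_locus",
    "score_percentile",
    "top_decile",
]


def write_candidates(candidates: Sequence, path: str | Path, format: str = "TSV") -> None:
    """Write an annotated candidate panel as TSV (all columns) or BED6.

    BED lines are ``chrom start end name score strand`` with the
    combined PWM score scaled to 0-1000; coordinates are 0-based
    half-open in both formats.  The TSV also reports 1-based inclusive
    coordinates.  An empty candidate list yields a header-only TSV or an
    empty BED.
    """
    fmt = format.upper()
    if fmt not in ("TSV", "BED"):
        raise ValueError(f"format must be TSV or BED, got {format!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if fmt == "TSV":
            fh.write("\t".join(_CANDIDATE_TSV_COLUMNS) + "\n")
        for cand in candidates:
            loc = cand.flanked.locus
            if fmt == "BED":
                fh.write(
                    f"{loc.chrom}\t{loc.start}\t{loc.end}\t{cand.locus_id}\t"
                    f"{_bed_score(cand.combined_score)}\t{loc.strand}\n"
                )
            else:
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            cand.locus_id,
                            loc.chrom,
                            loc.start,
                            loc.end,
                            loc.start + 1,
                            loc.end,
                            loc.strand,
                            loc.unit.bases,
                            loc.n_units,
                            f"{cand.match_5p.score:.4f}",
                            f"{cand.match_3p.score:.4f}",
                            f"{cand.combined_score:.4f}",
                            "" if cand.best_similarity_pct is None else f"{cand.best_similarity_pct:.2f}",
                            cand.best_similarity_locus or "",
                            "" if cand.score_percentile is None else f"{cand.score_percentile:.2f}",
                            "" if cand.top_decile is None else int(cand.top_decile),
                        )
                    )
                    + "\n"
                )


def write_loci(loci: Sequence, path: str | Path, format: str = "BED") -> None:
    """Write raw tandem-repeat loci as BED6 (score 0) or a small TSV."""
    fmt = format.upper()
    if fmt not in ("TSV", "BED"):
        raise ValueError(f"format must be TSV or BED, got {format!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if fmt == "TSV":
            fh.write("contig\tstart\tend\tstart_1based\tend_1based\tstrand\tunit\tn_units\n")
        for loc in loci:
            if fmt == "BED":
                fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.name}\t0\t{loc.strand}\n")
            else:
                fh.write(
                    f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.start + 1}\t{loc.end}\t"
                    f"{loc.strand}\t{loc.unit.bases}\t{loc.n_units}\n"
                )
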