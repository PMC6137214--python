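"""Maximal perfect tandem-repeat scanning and flank extraction.

The first stage of the candidate-discovery pipeline: given a repeat unit
(a tri- or tetranucleotide such as CTTT) find every maximal run of that
unit on a genome, then extract the fixed-width flanking sequences that
the motif model scores.

Conventions
-----------
* Coordinates are 0-based, half-open, on the forward strand.
* Only complete unit copies are counted; a trailing partial unit is not
  part of the locus.
* Repeats are perfect: a single mismatching base (including N) ends a
  run.
* The unit is matched verbatim on one strand; rotations of the unit
  (TTTC for CTTT) start at different offsets of the same biological
  tract and are deliberately not reported.  ``scan_genome`` can
  additionally scan the reverse complement, reporting minus-strand loci
  in forward coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "RepeatUnit",
    "TandemRepeatLocus",
    "FlankedLocus",
    "find_tandem_repeats",
    "scan_genome",
    "extract_flanks",
    "repeat_length_spectrum",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _minimal_period(s: str) -> int:
    for p in range(1, len(s)):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


@dataclass(frozen=True)
class RepeatUnit:
    """A tri- or tetranucleotide repeat unit, e.g. CTTT.

    The unit must be aperiodic (its minimal period equals its length):
    AAAA is really a mononucleotide repeat and ATAT a dinucleotide one,
    and accepting them would silently change the meaning of a
    tetranucleotide query.
    """

    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if len(bases) not in (3, 4):
            raise ValueError(f"repeat unit must be 3 or 4 nt, got {bases!r}")
        if set(bases) - set("ACGT"):
            raise ValueError(f"repeat unit {bases!r} contains non-ACGT characters")
        if _minimal_period(bases) != len(bases):
            raise ValueError(
                f"repeat unit {bases!r} is periodic (minimal period "
                f"{_minimal_period(bases)}); pass the minimal unit instead"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def reverse_complement(self) -> str:
        return reverse_complement(self.bases)


@dataclass(frozen=True)
class TandemRepeatLocus:
    """A maximal run of complete unit copies on a contig.

    ``[start, end)`` is 0-based half-open on the forward strand; for
    strand "−" the run of ``unit`` lies on the reverse complement but
    coordinates still index the forward sequence.
    """

    chrom: str
    start: int
    end: int
    unit: RepeatUnit
    n_units: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.unit) * self.n_units:
            raise ValueError(
                f"span {self.end - self.start} != {len(self.unit)} x {self.n_units}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        """Locus name in the C{chrom}R{n_units} convention."""
        chrom = self.chrom
        if chrom.lower().startswith("chr"):
            chrom = chrom[3:]
        return f"C{chrom}R{self.n_units}"


@dataclass(frozen=True)
class FlankedLocus:
    """A tandem-repeat locus together with its flanking sequences.

    Flanks are genome slices immediately adjacent to the repeat tract;
    ``complete_flanks`` is False when either slice was truncated by a
    contig edge.
    """

    locus: TandemRepeatLocus
    upstream_flank: str
    downstream_flank: str
    complete_flanks: bool = True
    repeat_seq: str = field(default="", compare=False)

    @property
    def region(self) -> str:
        """upstream flank + repeat tract + downstream flank."""
        tract = self.repeat_seq or self.locus.unit.bases * self.locus.n_units
        return self.upstream_flank + tract + self.downstream_flank


def _unit_match_mask(seq: str, unit: str) -> np.ndarray:
    """Boolean mask m[i] == True iff seq[i:i+k] == unit (vectorised)."""
    k = len(unit)
    n = len(seq)
    if n < k:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mask = np.ones(n - k + 1, dtype=bool)
    for j, base in enumerate(unit.encode("ascii")):
        mask &= arr[j : n - k + 1 + j] == base
    return mask


def find_tandem_repeats(
    record: SequenceRecord,
    unit: RepeatUnit | str,
    min_units: int,
) -> list[TandemRepeatLocus]:
    """Find every maximal perfect run of ``unit`` with >= min_units copies.

    Returns loci in ascending start order.  Runs are maximal: neither
    the k bases before the start nor the k bases after the end equal the
    unit.  Runs at other rotations/phases of the same tract are not
    reported (the unit is matched exactly as given, forward strand).
    """
    if isinstance(unit, str):
        unit = RepeatUnit(unit)
    if min_units < 2:
        raise ValueError(f"min_units must be >= 2, got {min_units}")
    seq = record.sequence
    k = len(unit)
    mask = _unit_match_mask(seq, unit.bases)
    loci: list[TandemRepeatLocus] = []
    i = 0
    limit = len(mask)
    while i < limit:
        if mask[i]:
            m = 1
            while i + m * k < limit and mask[i + m * k]:
                m += 1
            if m >= min_units:
                loci.append(
                    TandemRepeatLocus(
                        chrom=record.id,
                        start=i,
                        end=i + m * k,
                        unit=unit,
                        n_units=m,
                    )
                )
            i += m * k
        else:
            i += 1
    return loci


def scan_genome(
    records: Iterable[SequenceRecord],
    unit: RepeatUnit | str,
    min_units: int,
    scan_reverse: bool = False,
) -> list[TandemRepeatLocus]:
    """Scan every contig for tandem repeats of ``unit``.

    Forward-strand scans are always performed; with ``scan_reverse`` the
    reverse complement of each contig is scanned too and those loci are
    reported in forward coordinates with strand "−" (a CTTT run on the
    minus strand appears as AAAG on the forward sequence).  Within a
    contig loci are ordered by (start, strand).
    """
    if isinstance(unit, str):
        unit = RepeatUnit(unit)
    records = list(records)
    if not records:
        raise ValueError("no sequence records to scan")
    out: list[TandemRepeatLocus] = []
    for rec in records:
        loci = find_tandem_repeats(rec, unit, min_units)
        if scan_reverse:
            rc = SequenceRecord(rec.id, reverse_complement(rec.sequence))
            n = len(rec.sequence)
            for loc in find_tandem_repeats(rc, unit, min_units):
                loci.append(
                    TandemRepeatLocus(
                        chrom=rec.id,
                        start=n - loc.end,
                        end=n - loc.start,
                        unit=unit,
                        n_units=loc.n_units,
                        strand="-",
                    )
                )
        loci.sort(key=lambda l: (l.start, l.strand))
        out.extend(loci)
    return out


def extract_flanks(
    locus: TandemRepeatLocus,
    record: SequenceRecord,
    flank_len: int = 25,
) -> FlankedLocus:
    """Slice the flanking sequences immediately adjacent to a locus.

    The upstream flank is ``[start - flank_len, start)`` and the
    downstream flank ``[end, end + flank_len)``; slices truncated by a
    contig edge are kept and flagged via ``complete_flanks=False``.
    Flanks of minus-strand loci are reported in locus orientation
    (upstream = 5' of the repeat as read on its own strand).
    """
    if record.id != locus.chrom:
        raise ValueError(f"locus on {locus.chrom!r} but record is {record.id!r}")
    seq = record.sequence
    if not (0 <= locus.start and locus.end <= len(seq)):
        raise ValueError(f"locus [{locus.start},{locus.end}) outside contig of length {len(seq)}")
    up = seq[max(0, locus.start - flank_len) : locus.start]
    down = seq[locus.end : locus.end + flank_len]
    tract = seq[locus.start : locus.end]
    if locus.strand == "-":
        up, down = reverse_complement(down), reverse_complement(up)
        tract = reverse_complement(tract)
    complete = len(up) == flank_len and len(down) == flank_len
    return FlankedLocus(
        locus=locus,
        upstream_flank=up,
        downstream_flank=down,
        complete_flanks=complete,
        repeat_seq=tract,
    )


def repeat_length_spectrum(
    records: Iterable[SequenceRecord],
    unit: RepeatUnit | str,
    min_units: int = 10,
    max_units: int = 25,
) -> dict[tuple[str, object], int]:
    """Count maximal loci per contig per exact unit count.

    Returns a mapping ``(contig, n_units) -> count`` for n_units in
    [min_units, max_units]; loci longer than max_units are pooled under
    the key ``(contig, "overflow")``.  The spectrum totals equal the
    number of loci ``scan_genome`` reports at the same min_units.
    """
    if min_units > max_units:
        raise ValueError("min_units must be <= max_units")
    spectrum: dict[tuple[str, object], int] = {}
    for loc in scan_genome(records, unit, min_units):
        key: tuple[str, object]
        if loc.n_units > max_units:
            key = (loc.chrom, "overflow")
        else:
            key = (loc.chrom, loc.n_units)
        spectrum[key] = spectrum.get(key, 0) + 1
    return spectrum
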