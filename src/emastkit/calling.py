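"""Per-marker instability and per-tumor EMAST calling from repeat counts.

Input is a long-format table of repeat-unit counts per marker, sample
and tissue (normal / tumor / parental), together with the published
reference count of each marker.  Three calls are made:

* normal-tissue instability — any mouse's normal count deviates from
  the published reference count (an alternative across-mice definition
  is available);
* per-marker EMAST — the set of mice whose tumor count differs from
  their own matched normal count (missing cells are skipped, never
  imputed or called);
* per-tumor EMAST status — a mouse is EMAST-positive when at least a
  configured number of panel markers (default 1) call EMAST in it;
  control markers not identified by the discovery algorithm are
  excluded from this classification by default.

Alignment-level deltas: because the repeat unit is 4 nt, an indel
between two sequences of the same locus must be a gap of 4 or a
multiple of 4 nucleotides; any other tract-length difference is
flagged as a non-unit indel rather than silently rounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repeats import RepeatUnit, find_tandem_repeats
from .io import SequenceRecord

__all__ = [
    "MarkerCounts",
    "MarkerCalls",
    "PanelSummary",
    "repeat_count_delta",
    "call_normal_instability",
    "call_emast",
    "classify_tumors",
    "summarize_panel",
    "read_count_table",
    "write_calls",
    "load_table1",
]


@dataclass(frozen=True)
class MarkerCounts:
    """Repeat-unit counts for one marker across mice and tissues."""

    marker_id: str
    published_n_units: int
    normal: Mapping[str, int]
    tumor: Mapping[str, int]
    parental: Mapping[str, int] | None = None
    algorithm_identified: bool = True

    def __post_init__(self) -> None:
        if self.published_n_units < 1:
            raise ValueError(f"{self.marker_id}: published_n_units must be >= 1")
        for tissue, counts in (("normal", self.normal), ("tumor", self.tumor)):
            for sample, n in counts.items():
                if n < 1:
                    raise ValueError(
                        f"{self.marker_id}: non-positive {tissue} count {n} for sample {sample}"
                    )


@dataclass(frozen=True)
class MarkerCalls:
    """Per-marker outcome of the instability rules."""

    marker_id: str
    normal_instability: bool
    emast_mice: frozenset[str]

    @property
    def any_instability(self) -> bool:
        return self.normal_instability or bool(self.emast_mice)


@dataclass(frozen=True)
class PanelSummary:
    """Aggregate calls over a marker panel (controls tallied separately)."""

    n_markers: int
    n_markers_emast: int
    n_markers_normal_instability: int
    n_markers_overlap: int
    n_markers_any_instability: int
    emast_positive_mice: frozenset[str]
    marker_calls: tuple[MarkerCalls, ...]
    control_calls: tuple[MarkerCalls, ...] = ()

    @property
    def n_controls_any_instability(self) -> int:
        return sum(1 for c in self.control_calls if c.any_instability)

    def to_dict(self) -> dict:
        return {
            "n_markers": self.n_markers,
            "n_markers_emast": self.n_markers_emast,
            "n_markers_normal_instability": self.n_markers_normal_instability,
            "n_markers_overlap": self.n_markers_overlap,
            "n_markers_any_instability": self.n_markers_any_instability,
            "emast_positive_mice": sorted(self.emast_positive_mice),
            "n_controls": len(self.control_calls),
            "n_controls_any_instability": self.n_controls_any_instability,
        }


def _tract_length_nt(seq: str, unit: RepeatUnit) -> tuple[int, int]:
    """(complete unit count, tract length in nt incl. partial trailing unit).

    The sequence must contain exactly one maximal run of the unit with
    at least 2 copies.
    """
    loci = find_tandem_repeats(SequenceRecord("q", seq), unit, min_units=2)
    if len(loci) != 1:
        raise ValueError(
            f"expected exactly one repeat tract of {unit} with >= 2 units, found {len(loci)}"
        )
    loc = loci[0]
    # extend over any partial trailing unit so non-unit indels are visible
    tract_nt = loc.end - loc.start
    k = len(unit)
    j = loc.end
    while j < len(seq) and seq[j] == unit.bases[(j - loc.start) % k]:
        tract_nt += 1
        j += 1
    i = loc.start - 1
    phase = k - 1
    while i >= 0 and seq[i] == unit.bases[phase]:
        tract_nt += 1
        i -= 1
        phase = (phase - 1) % k
    return loc.n_units, tract_nt


def repeat_count_delta(reference_seq: str, sample_seq: str, unit: RepeatUnit | str) -> int:
    """Repeat-unit count difference (sample − reference) between two sequences.

    Each sequence must contain one maximal tract of ``unit``; the
    implied alignment gap is ``len(unit) x |delta|`` nucleotides.  A
    tract-length difference that is not a whole number of units (e.g. a
    3-nt indel in a tetranucleotide tract) raises, since only unit-sized
    gaps indicate repeat-number change.
    """
    if isinstance(unit, str):
        unit = RepeatUnit(unit)
    n_ref, nt_ref = _tract_length_nt(reference_seq.upper(), unit)
    n_smp, nt_smp = _tract_length_nt(sample_seq.upper(), unit)
    diff_nt = nt_smp - nt_ref
    if diff_nt % len(unit) != 0:
        raise ValueError(
            f"tract lengths differ by {abs(diff_nt)} nt, not a multiple of the "
            f"{len(unit)}-nt unit: non-unit indel"
        )
    return n_smp - n_ref


def call_normal_instability(marker: MarkerCounts, mode: str = "vs_published") -> bool:
    """Is the marker unstable across normal tissue samples?

    ``vs_published`` (default): any present normal count differs from
    the published reference count.  ``across_mice``: the present normal
    counts are not all identical.  Both definitions agree on every
    marker of the packaged reference table.
    """
    counts = [n for n in marker.normal.values()]
    if not counts:
        raise ValueError(f"{marker.marker_id}: no normal counts")
    if mode == "vs_published":
        return any(n != marker.published_n_units for n in counts)
    if mode == "across_mice":
        return len(set(counts)) > 1
    raise ValueError(f"unknown mode {mode!r}")


def call_emast(marker: MarkerCounts) -> frozenset[str]:
    """Mice whose tumor repeat count differs from their matched normal.

    Only mice with both counts present are comparable; a marker with no
    comparable pair is an error rather than a silent negative.
    """
    comparable = set(marker.normal) & set(marker.tumor)
    if not comparable:
        raise ValueError(f"{marker.marker_id}: no mouse has both normal and tumor counts")
    return frozenset(m for m in comparable if marker.tumor[m] != marker.normal[m])


def classify_tumors(
    markers: Sequence[MarkerCounts],
    min_unstable_markers: int = 1,
    include_controls: bool = False,
) -> frozenset[str]:
    """Mice called EMAST-positive: >= min_unstable_markers markers unstable.

    Controls (markers not identified by the discovery algorithm) are
    excluded from the panel unless requested.
    """
    panel = [m for m in markers if m.algorithm_identified or include_controls]
    if not panel:
        raise ValueError("empty marker panel")
    per_mouse: dict[str, int] = {}
    for marker in panel:
        for mouse in call_emast(marker):
            per_mouse[mouse] = per_mouse.get(mouse, 0) + 1
    if min_unstable_markers <= 0:
        mice = set()
        for marker in panel:
            mice |= set(marker.normal) & set(marker.tumor)
        return frozenset(mice)
    return frozenset(m for m, k in per_mouse.items() if k >= min_unstable_markers)


def summarize_panel(
    markers: Sequence[MarkerCounts],
    min_unstable_markers: int = 1,
    normal_mode: str = "vs_published",
) -> PanelSummary:
    """Aggregate per-marker calls over the algorithm-identified panel."""
    if not markers:
        raise ValueError("no markers to summarize")
    panel = [m for m in markers if m.algorithm_identified]
    controls = [m for m in markers if not m.algorithm_identified]

    def calls_for(marker: MarkerCounts) -> MarkerCalls:
        return MarkerCalls(
            marker_id=marker.marker_id,
            normal_instability=call_normal_instability(marker, mode=normal_mode),
            emast_mice=call_emast(marker),
        )

    marker_calls = tuple(calls_for(m) for m in panel)
    control_calls = tuple(calls_for(m) for m in controls)
    n_emast = sum(1 for c in marker_calls if c.emast_mice)
    n_normal = sum(1 for c in marker_calls if c.normal_instability)
    n_overlap = sum(1 for c in marker_calls if c.normal_instability and c.emast_mice)
    n_any = sum(1 for c in marker_calls if c.any_instability)
    positive = classify_tumors(panel, min_unstable_markers=min_unstable_markers) if panel else frozenset()
    return PanelSummary(
        n_markers=len(panel),
        n_markers_emast=n_emast,
        n_markers_normal_instability=n_normal,
        n_markers_overlap=n_overlap,
        n_markers_any_instability=n_any,
        emast_positive_mice=positive,
        marker_calls=marker_calls,
        control_calls=control_calls,
    )


# ---------------------------------------------------------------------------
# Table I/O

_TABLE_COLUMNS = [
    "marker_id",
    "published_n_units",
    "sample_id",
    "tissue",
    "n_units",
    "algorithm_identified",
]


def read_count_table(path: str | Path) -> list[MarkerCounts]:
    """Read a long-format repeat-count TSV into MarkerCounts records.

    Columns: marker_id, published_n_units, sample_id, tissue in
    {normal, tumor, parental}, n_units (blank = missing, skipped),
    algorithm_identified in {0, 1}.  Marker order follows first
    appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: count table has no rows")
    markers: list[MarkerCounts] = []
    for marker_id, grp in df.groupby("marker_id", sort=False):
        published = int(grp["published_n_units"].iloc[0])
        algo = bool(int(grp["algorithm_identified"].iloc[0]))
        tissues: dict[str, dict[str, int]] = {"normal": {}, "tumor": {}, "parental": {}}
        for row in grp.itertuples(index=False):
            tissue = str(row.tissue).lower()
            if tissue not in tissues:
                raise ValueError(f"{marker_id}: unknown tissue {row.tissue!r}")
            if pd.isna(row.n_units) or str(row.n_units).strip() == "":
                continue
            tissues[tissue][str(row.sample_id)] = int(float(row.n_units))
        markers.append(
            MarkerCounts(
                marker_id=str(marker_id),
                published_n_units=published,
                normal=tissues["normal"],
                tumor=tissues["tumor"],
                parental=tissues["parental"] or None,
                algorithm_identified=algo,
            )
        )
    return markers


def write_calls(
    summary: PanelSummary,
    calls_path: str | Path | None = None,
    summary_path: str | Path | None = None,
) -> None:
    """Write per-marker calls as TSV and the panel summary as JSON."""
    if calls_path is not None:
        with open(calls_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("marker_id\tis_control\tnormal_instability\temast_mice\tany_instability\n")
            for is_control, calls in ((0, summary.marker_calls), (1, summary.control_calls)):
                for c in calls:
                    fh.write(
                        f"{c.marker_id}\t{is_control}\t{int(c.normal_instability)}\t"
                        f"{','.join(sorted(c.emast_mice))}\t{int(c.any_instability)}\n"
                    )
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps(summary.to_dict(), indent=2) + "\n", encoding="utf-8"
        )


def load_table1() -> list[MarkerCounts]:
    """The packaged reference repeat-count table (seven discovered CTTT
    markers, two ATCT controls, and parental counts for C10R18)."""
    with resources.as_file(resources.files("emastkit.data") / "table1.tsv") as p:
        return read_count_table(p)
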