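"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: genomes with
planted tandem repeats whose flanks do or do not carry the 11-nt
motifs, flank training sets with a motif planted in a chosen fraction
of sequences (the reference panels show the motif in 6 of 7 flanks),
and tumor/normal repeat-count tables with planted instability events.
Each generator is a pure function of its arguments including the seed,
and returns a truth record alongside the data so tests can check
recall exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calling import MarkerCounts
from .io import SequenceRecord
from .motifs import ALPHABET
from .repeats import RepeatUnit, find_tandem_repeats

__all__ = [
    "PlantSpec",
    "TruthSet",
    "generate_genome",
    "generate_flank_set",
    "generate_count_table",
]

DEFAULT_BASE_FREQS = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantSpec:
    """One repeat locus to plant: unit, copy number, motif flag, position."""

    unit: RepeatUnit
    n_units: int
    with_motifs: bool = True
    contig: str = "chr1"
    position: int | None = None


@dataclass
class TruthSet:
    """Ground truth emitted by the generators."""

    loci: list[dict] = field(default_factory=list)  # chrom/start/end/unit/n_units/with_motifs
    motif_sites: list[dict] = field(default_factory=list)  # seq index or locus, side, offset
    instability_events: list[dict] = field(default_factory=list)  # marker/sample/kind/delta


def _random_bases(rng: np.random.Generator, n: int, freqs: Sequence[float]) -> str:
    return "".join(rng.choice(list(ALPHABET), size=n, p=list(freqs)))


def _guard_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in ALPHABET if b != avoid]
    return choices[rng.integers(len(choices))]


def generate_genome(
    length: int,
    plants: Sequence[PlantSpec],
    motif_5p: str,
    motif_3p: str,
    base_freqs: Sequence[float] = DEFAULT_BASE_FREQS,
    flank_len: int = 25,
    seed: int = 0,
    verify: bool = True,
) -> tuple[list[SequenceRecord], TruthSet]:
    """Random genome with planted repeat tracts and optional flank motifs.

    Background bases are i.i.d. from ``base_freqs``.  Each plant writes
    ``unit x n_units`` at its position; when ``with_motifs`` the exact
    consensus motifs are embedded inside the adjacent ``flank_len``-nt
    flanks (at a seeded random offset that keeps the unit-length bases
    nearest the tract free).  The bases immediately bordering each
    tract are set so no tract extends beyond its planted length, and a
    final self-check (``verify``) re-scans the genome to confirm that
    the maximal-repeat calls match the planted truth exactly.

    Plants on the same contig must be separated by at least
    ``flank_len + len(motif)`` so the flank and truth annotations never
    collide.  Positions left as None are drawn uniformly subject to
    that rule.
    """
    rng = np.random.default_rng(seed)
    plants = list(plants)
    contigs = sorted({p.contig for p in plants}) or ["chr1"]
    truth = TruthSet()
    records: list[SequenceRecord] = []
    min_sep = flank_len + max(len(motif_5p), len(motif_3p), 1)
    for contig in contigs:
        seq = list(_random_bases(rng, length, base_freqs))
        mine = [p for p in plants if p.contig == contig]
        # resolve positions
        placed: list[tuple[int, int, PlantSpec]] = []
        for p in mine:
            span = len(p.unit) * p.n_units
            if p.position is not None:
                start = p.position
            else:
                for _ in range(1000):
                    start = int(rng.integers(flank_len + 1, length - span - flank_len - 1))
                    if all(
                        start + span + min_sep <= s or e + min_sep <= start
                        for s, e, _ in placed
                    ):
                        break
                else:
                    raise ValueError("could not place plant without collision")
            end = start + span
            if start < flank_len or end + flank_len > length:
                raise ValueError(f"plant [{start},{end}) leaves no room for flanks in contig of {length}")
            for s, e, _ in placed:
                if not (end + min_sep <= s or e + min_sep <= start):
                    raise ValueError("plants overlap or are closer than the separation rule allows")
            placed.append((start, end, p))
        placed.sort()
        for start, end, p in placed:
            k = len(p.unit)
            seq[start:end] = list(p.unit.bases * p.n_units)
            # guard bases: break any accidental extension of the tract
            seq[start - 1] = _guard_base(rng, p.unit.bases[-1])
            if end < length:
                seq[end] = _guard_base(rng, p.unit.bases[0])
            if p.with_motifs:
                # 5' motif inside [start-flank_len, start-k): keeps the
                # guard base and the tract-adjacent unit-length free
                w5 = len(motif_5p)
                off5 = int(rng.integers(0, flank_len - w5 - k + 1))
                pos5 = start - flank_len + off5
                seq[pos5 : pos5 + w5] = list(motif_5p)
                w3 = len(motif_3p)
                off3 = int(rng.integers(k, flank_len - w3 + 1))
                pos3 = end + off3
                seq[pos3 : pos3 + w3] = list(motif_3p)
                truth.motif_sites.append(
                    {"contig": contig, "side": "5p", "offset": pos5, "seq": motif_5p}
                )
                truth.motif_sites.append(
                    {"contig": contig, "side": "3p", "offset": pos3, "seq": motif_3p}
                )
                # motifs may have re-created an extension next to the tract
                if "".join(seq[start - k : start]) == p.unit.bases:
                    seq[start - 1] = _guard_base(rng, p.unit.bases[-1])
                if "".join(seq[end : end + k]) == p.unit.bases:
                    seq[end] = _guard_base(rng, p.unit.bases[0])
            truth.loci.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "unit": p.unit.bases,
                    "n_units": p.n_units,
                    "with_motifs": p.with_motifs,
                }
            )
        records.append(SequenceRecord(contig, "".join(seq)))

    if verify:
        units = {p.unit.bases for p in plants}
        for unit in units:
            want_min = min(p.n_units for p in plants if p.unit.bases == unit)
            found = {
                (r.id, l.start, l.end, l.n_units)
                for r in records
                for l in find_tandem_repeats(r, RepeatUnit(unit), min_units=min(want_min, 10))
            }
            want = {
                (t["contig"], t["start"], t["end"], t["n_units"])
                for t in truth.loci
                if t["unit"] == unit
            }
            if found != want:
                raise AssertionError(
                    f"generator self-check failed for unit {unit}: scan found {found ^ want} "
                    "unexpected/missing loci; choose another seed"
                )
    return records, truth


def generate_flank_set(
    motif: str,
    n_seqs: int = 7,
    flank_len: int = 25,
    occurrence: float = 6 / 7,
    mutations_per_site: int = 0,
    base_freqs: Sequence[float] = DEFAULT_BASE_FREQS,
    seed: int = 0,
) -> tuple[list[str], TruthSet]:
    """Flank training set with the motif planted in a fraction of sequences.

    ``round(occurrence * n_seqs)`` sequences receive the motif at a
    seeded random offset, with ``mutations_per_site`` random point
    substitutions applied per planted site; the remainder are pure
    background.  Which sequences carry the motif is itself randomised.
    """
    w = len(motif)
    if flank_len < w:
        raise ValueError(f"flank_len {flank_len} shorter than motif width {w}")
    if not 0.0 <= occurrence <= 1.0:
        raise ValueError("occurrence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_planted = round(occurrence * n_seqs)
    carriers = set(rng.choice(n_seqs, size=n_planted, replace=False).tolist())
    seqs: list[str] = []
    truth = TruthSet()
    for i in range(n_seqs):
        s = list(_random_bases(rng, flank_len, base_freqs))
        if i in carriers:
            off = int(rng.integers(0, flank_len - w + 1))
            site = list(motif)
            if mutations_per_site > 0:
                pos = rng.choice(w, size=min(mutations_per_site, w), replace=False)
                for j in pos:
                    site[j] = _guard_base(rng, site[j])
            s[off : off + w] = site
            truth.motif_sites.append({"seq_index": i, "offset": off, "seq": "".join(site)})
        seqs.append("".join(s))
    return seqs, truth


def generate_count_table(
    n_markers: int,
    n_mice: int,
    p_normal_instability: float,
    p_emast: float,
    delta_distribution: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[list[MarkerCounts], TruthSet]:
    """Repeat-count tables with planted instability.

    Mirrors the structure of the reference table: per marker a
    published count in 14-18; each mouse's normal count is shifted from
    published with probability ``p_normal_instability``, and its tumor
    count is shifted from its own normal with probability ``p_emast``.
    Shifts are drawn from ``delta_distribution`` over {-2,-1,+1,+2}
    (default uniform); zero is excluded so every planted event is a
    real call.
    """
    for name, p in (("p_normal_instability", p_normal_instability), ("p_emast", p_emast)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if delta_distribution is None:
        delta_distribution = {-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25}
    deltas = sorted(delta_distribution)
    if 0 in deltas:
        raise ValueError("delta_distribution must not include 0")
    probs = np.array([delta_distribution[d] for d in deltas], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    truth = TruthSet()
    markers: list[MarkerCounts] = []
    mice = [str(i + 1) for i in range(n_mice)]
    for mi in range(n_markers):
        published = int(rng.integers(14, 19))
        marker_id = f"M{mi + 1}R{published}"
        normal: dict[str, int] = {}
        tumor: dict[str, int] = {}
        for mouse in mice:
            n = published
            if rng.random() < p_normal_instability:
                d = int(rng.choice(deltas, p=probs))
                n = max(2, published + d)
                truth.instability_events.append(
                    {"marker": marker_id, "sample": mouse, "kind": "normal", "delta": n - published}
                )
            t = n
            if rng.random() < p_emast:
                d = int(rng.choice(deltas, p=probs))
                t = max(2, n + d)
                if t == n:  # clipping collapsed the shift; force a minimal one
                    t = n + 1
                truth.instability_events.append(
                    {"marker": marker_id, "sample": mouse, "kind": "emast", "delta": t - n}
                )
            normal[mouse] = n
            tumor[mouse] = t
        markers.append(
            MarkerCounts(
                marker_id=marker_id,
                published_n_units=published,
                normal=normal,
                tumor=tumor,
                algorithm_identified=True,
            )
        )
    return markers, truth
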