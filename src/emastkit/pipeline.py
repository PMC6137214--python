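"""The candidate decision chain: motif filter, similarity, ranking, selection.

Flanked tandem-repeat loci become candidates only when *both* flanks
contain the trained motif (best log-odds window at or above the model
threshold).  Candidates are then compared with a panel of known
unstable loci by global-alignment percent similarity over the
flank + repeat-tract + flank region, ranked into percentiles of their
combined PWM score, and the reportable panel is selected by similarity
(default >= 85%) and repeat count (default >= 13 units).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .io import KnownLocusRecord
from .motifs import MotifMatch, MotifModel, scan_flank
from .repeats import FlankedLocus

__all__ = [
    "CandidateLocus",
    "filter_by_motifs",
    "percent_similarity",
    "global_alignment",
    "annotate_similarity",
    "rank_candidates",
    "select_candidates",
    "assign_locus_ids",
]

# Global-alignment scoring used for percent similarity.  End gaps are
# penalised like any other gap; the traceback tie-break (diagonal, then
# up, then left) makes the reported alignment — and hence the identity
# fraction — deterministic.
MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass(frozen=True)
class CandidateLocus:
    """A flanked locus that passed the dual-flank motif filter."""

    flanked: FlankedLocus
    match_5p: MotifMatch
    match_3p: MotifMatch
    combined_score: float
    locus_id: str = ""
    best_similarity_pct: float | None = None
    best_similarity_locus: str | None = None
    score_percentile: float | None = None
    top_decile: bool | None = None

    @property
    def region(self) -> str:
        return self.flanked.region

    @property
    def n_units(self) -> int:
        return self.flanked.locus.n_units


def filter_by_motifs(
    loci: Sequence[FlankedLocus],
    model: MotifModel,
    require_complete_flanks: bool = True,
) -> list[CandidateLocus]:
    """Keep loci whose two flanks both score at or above threshold.

    The 5' model is scanned against the upstream flank and the 3' model
    against the downstream flank; the combined score is the sum of the
    two best window scores.  Loci with incomplete flanks are dropped
    when ``require_complete_flanks`` (they cannot be checked on both
    sides); flanks shorter than the motif width can never pass.
    """
    out: list[CandidateLocus] = []
    for fl in loci:
        if require_complete_flanks and not fl.complete_flanks:
            continue
        m5 = scan_flank(fl.upstream_flank, model.pwm_5p)
        m3 = scan_flank(fl.downstream_flank, model.pwm_3p)
        if m5 is None or m3 is None:
            continue
        if m5.score >= model.threshold_5p and m3.score >= model.threshold_3p:
            out.append(
                CandidateLocus(
                    flanked=fl,
                    match_5p=m5,
                    match_3p=m3,
                    combined_score=m5.score + m3.score,
                )
            )
    return assign_locus_ids(out)


def assign_locus_ids(candidates: list[CandidateLocus]) -> list[CandidateLocus]:
    """Name candidates C{contig}R{n_units}; collisions get .2, .3, ..."""
    seen: dict[str, int] = {}
    named = []
    for cand in candidates:
        base = cand.flanked.locus.name
        seen[base] = seen.get(base, 0) + 1
        name = base if seen[base] == 1 else f"{base}.{seen[base]}"
        named.append(replace(cand, locus_id=name))
    return named


def global_alignment(a: str, b: str) -> tuple[int, str, str]:
    """Needleman–Wunsch with match +1 / mismatch −1 / gap −2, end gaps penalised.

    Returns (score, aligned_a, aligned_b).  Traceback prefers diagonal,
    then up (gap in ``b``), then left (gap in ``a``), so the alignment
    is deterministic.
    """
    if not a or not b:
        raise ValueError("global_alignment requires two non-empty sequences")
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=diag, 1=up, 2=left
    score[0, :] = GAP * np.arange(m + 1)
    score[:, 0] = GAP * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    sub = np.where(aa[:, None] == bb[None, :], MATCH, MISMATCH).astype(np.int32)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        row = score[i]
        prow = ptr[i]
        prev = row[0]
        for j in range(1, m + 1):
            d = diag[j - 1]
            u = up[j - 1]
            l = prev + GAP
            if d >= u and d >= l:
                best, p = d, 0
            elif u >= l:
                best, p = u, 1
            else:
                best, p = l, 2
            row[j] = best
            prow[j] = p
            prev = best
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return int(score[n, m]), "".join(reversed(out_a)), "".join(reversed(out_b))


def percent_similarity(candidate_region: str, known_region: str) -> float:
    """Percent identity of the global alignment of two regions (0–100).

    100 x (matched columns) / (alignment length), with the alignment
    produced by :func:`global_alignment`.  Identical sequences score
    exactly 100.0.
    """
    _, ala, alb = global_alignment(candidate_region.upper(), known_region.upper())
    matches = sum(1 for x, y in zip(ala, alb) if x == y and x != "-")
    return 100.0 * matches / len(ala)


def annotate_similarity(
    candidates: Sequence[CandidateLocus],
    panel: Sequence[KnownLocusRecord],
) -> list[CandidateLocus]:
    """Attach the best percent similarity to any panel locus.

    Ties keep the first panel entry in input order.
    """
    if not panel:
        raise ValueError("known-locus panel is empty")
    out = []
    for cand in candidates:
        best_pct = -1.0
        best_id = None
        region = cand.region
        for known in panel:
            pct = percent_similarity(region, known.region)
            if pct > best_pct:
                best_pct, best_id = pct, known.locus_id
        out.append(replace(cand, best_similarity_pct=best_pct, best_similarity_locus=best_id))
    return out


def rank_candidates(candidates: Sequence[CandidateLocus]) -> list[CandidateLocus]:
    """Percentile-rank candidates by combined PWM score.

    percentile = 100 x rank / n with average ranks for ties; the top
    decile flag marks scores strictly above the 90th percentile ("within
    the top tenth percentile").  Percentiles depend only on the score
    multiset, not on input order.
    """
    if not candidates:
        raise ValueError("need at least one candidate to rank")
    scores = np.array([c.combined_score for c in candidates])
    pct = 100.0 * rankdata(scores, method="average") / len(scores)
    return [
        replace(c, score_percentile=float(p), top_decile=bool(p > 90.0))
        for c, p in zip(candidates, pct)
    ]


def select_candidates(
    candidates: Sequence[CandidateLocus],
    min_similarity_pct: float = 85.0,
    min_units: int = 13,
) -> list[CandidateLocus]:
    """Final panel: similarity >= threshold and repeat count >= threshold.

    Output is sorted by (contig, start).
    """
    kept = [
        c
        for c in candidates
        if c.best_similarity_pct is not None
        and c.best_similarity_pct >= min_similarity_pct
        and c.n_units >= min_units
    ]
    kept.sort(key=lambda c: (c.flanked.locus.chrom, c.flanked.locus.start))
    return kept
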