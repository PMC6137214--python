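"""Position weight matrices and EM motif discovery for repeat flanks.

Unstable tetranucleotide repeats carry characteristic 11-nt motifs in
the 25 nt immediately flanking the tract.  This module learns one PWM
per flank side from a training panel of known unstable loci, using a
ZOOPS ("zero or one occurrence per sequence") expectation-maximisation
search — appropriate because the flanking motif is present in most but
not all training sequences — and scores new flanks by summed log-odds
(bits) against a 0-order background.

The discovered model is serialised both as MEME minimal text (so
third-party scanners can consume the matrices) and as JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io import KnownLocusRecord

__all__ = [
    "ALPHABET",
    "PositionWeightMatrix",
    "MotifMatch",
    "MotifModel",
    "build_pwm",
    "log_odds_score",
    "scan_flank",
    "discover_motif",
    "train_motif_model",
    "write_meme",
    "read_meme",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# EM convergence: stop when the objective improves by less than this,
# or after this many iterations.
EM_TOL = 1e-6
EM_MAX_ITER = 200


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-column base probabilities of a fixed-width motif.

    ``probs`` is a 4 x width matrix in A,C,G,T row order; every column
    sums to 1.  ``background`` holds the 0-order base frequencies the
    log-odds scores are taken against.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"probs must be 4 x width, got shape {probs.shape}")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 frequencies summing to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x width matrix of log2(p / background), rows A,C,G,T."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    @property
    def information_content(self) -> float:
        """Total relative entropy vs background, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background[:, None])
        return float(np.where(self.probs > 0, terms, 0.0).sum())


@dataclass(frozen=True)
class MotifMatch:
    """Best-scoring motif window within a scanned flank."""

    offset: int
    score: float
    matched_seq: str


@dataclass(frozen=True)
class MotifModel:
    """Paired 5' / 3' flank PWMs with acceptance thresholds (bits)."""

    pwm_5p: PositionWeightMatrix
    pwm_3p: PositionWeightMatrix
    threshold_5p: float
    threshold_3p: float
    evalue_5p: float = float("nan")
    evalue_3p: float = float("nan")

    def __post_init__(self) -> None:
        if self.pwm_5p.width != self.pwm_3p.width:
            raise ValueError("5' and 3' PWMs must share a width")
        if not (math.isfinite(self.threshold_5p) and math.isfinite(self.threshold_3p)):
            # -inf thresholds are allowed as an explicit "filter off" state
            if not (self.threshold_5p == float("-inf") or self.threshold_3p == float("-inf")):
                raise ValueError("thresholds must be finite")

    @property
    def width(self) -> int:
        return self.pwm_5p.width


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and N (or anything else) to 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(base)] = idx
    return out


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
) -> PositionWeightMatrix:
    """Estimate a PWM from aligned equal-length sites.

    probs[b][j] = (count(b, j) + pseudocount * background[b]) / (n_sites + pseudocount).
    A zero pseudocount is allowed only when no column is degenerate.
    """
    if not sites:
        raise ValueError("need at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((4, width))
    for site in sites:
        enc = _encode(site.upper())
        if (enc > 3).any():
            raise ValueError(f"site {site!r} contains non-ACGT characters")
        for j, b in enumerate(enc):
            counts[b, j] += 1
    probs = (counts + pseudocount * bg[:, None]) / (len(sites) + pseudocount)
    # with pseudocount 0 unobserved bases get probability 0 and score -inf;
    # discovery and scanning always use a positive pseudocount
    return PositionWeightMatrix(probs=probs, background=bg, pseudocount=pseudocount)


def log_odds_score(pwm: PositionWeightMatrix, window: str) -> float:
    """Sum over columns of log2(p[base,j] / background[base]), in bits.

    An N in the window contributes 0 for its column (no evidence either
    way).
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    enc = _encode(window.upper())
    lo = pwm.log_odds
    score = 0.0
    for j, b in enumerate(enc):
        if b <= 3:
            score += lo[b, j]
    return float(score)


def scan_flank(flank: str, pwm: PositionWeightMatrix) -> MotifMatch | None:
    """Best-scoring window of the flank; ties go to the smallest offset.

    Returns None when the flank is shorter than the motif width.  Scans
    the forward strand only — flanks arrive already oriented with their
    locus.
    """
    flank = flank.upper()
    w = pwm.width
    n = len(flank) - w + 1
    if n <= 0:
        return None
    enc = _encode(flank)
    lo = np.vstack([pwm.log_odds, np.zeros(pwm.width)])  # row 4 = N contributes 0
    idx = np.arange(n)[:, None] + np.arange(w)[None, :]
    scores = lo[enc[idx], np.arange(w)[None, :]].sum(axis=1)
    # smallest offset among windows tied with the maximum; the tolerance
    # makes the tie rule robust to float summation order
    top = scores.max()
    best = int(np.flatnonzero(scores > top - 1e-9)[0])
    return MotifMatch(offset=best, score=float(scores[best]), matched_seq=flank[best : best + w])


def _background_from(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        enc = _encode(s.upper())
        for b in range(4):
            counts[b] += int((enc == b).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # tiny floor keeps log-odds finite even if a base is absent
    counts = counts + 0.1
    return counts / counts.sum()


@dataclass
class DiscoveryResult:
    """Outcome of one ZOOPS-EM motif search."""

    pwm: PositionWeightMatrix
    sites: list[tuple[int, int, str]]  # (sequence index, offset, site sequence)
    evalue: float
    log_likelihood: float
    ll_trace: list[float] = field(default_factory=list)
    gamma: float = 0.0  # fitted per-sequence occurrence probability

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


def _zoops_em(
    windows: list[np.ndarray],
    seed_word: np.ndarray,
    width: int,
    bg: np.ndarray,
    pseudocount: float,
) -> tuple[np.ndarray, float, float, list[float], list[np.ndarray]]:
    """Run ZOOPS EM from one seed word.

    Returns (probs, gamma, objective, trace, per-sequence posteriors).
    The tracked objective is the data log-likelihood plus the Dirichlet
    pseudocount prior on the PWM, which EM increases monotonically.
    """
    n_seqs = len(windows)
    # seed PWM: consensus base 0.7, the rest proportional to background
    probs = np.zeros((4, width))
    for j in range(width):
        rest = bg.copy()
        rest[seed_word[j]] = 0.0
        rest = rest / rest.sum() * 0.3
        probs[:, j] = rest
        probs[seed_word[j], j] += 0.7
    gamma = 0.75
    log_bg = np.log(bg)
    alpha = pseudocount * bg  # Dirichlet pseudocounts per column

    prev_obj = -np.inf
    trace: list[float] = []
    Z_list: list[np.ndarray] = []
    for _ in range(EM_MAX_ITER):
        log_probs = np.log(probs)
        # E-step: per-sequence site posteriors
        Z_list = []
        loglik = 0.0
        exp_counts = np.zeros((4, width))
        exp_sites = 0.0
        for win in windows:
            m = win.shape[0]
            # log likelihood-ratio of each window under motif vs background
            llr = (
                log_probs[win, np.arange(width)[None, :]].sum(axis=1)
                - log_bg[win].sum(axis=1)
            )
            # P(site at j) = gamma/m * LR_j ; P(no site) = 1 - gamma
            a = math.log(gamma / m) + llr
            a_max = max(a.max(), math.log1p(-gamma) if gamma < 1 else -np.inf)
            denom = np.exp(a - a_max).sum() + (math.exp(math.log1p(-gamma) - a_max) if gamma < 1 else 0.0)
            log_denom = a_max + math.log(denom)
            Z = np.exp(a - log_denom)
            Z_list.append(Z)
            loglik += log_denom  # background log-prob of the full sequence is constant; omitted
            exp_sites += Z.sum()
            for j in range(width):
                np.add.at(exp_counts[:, j], win[:, j], Z)
        prior = float((alpha[:, None] * np.log(probs)).sum())
        obj = loglik + prior
        trace.append(obj)
        if obj - prev_obj < EM_TOL and len(trace) > 1:
            break
        prev_obj = obj
        # M-step
        probs = (exp_counts + alpha[:, None]) / (exp_sites + pseudocount)
        probs = np.clip(probs, 1e-12, None)
        probs /= probs.sum(axis=0, keepdims=True)
        gamma = min(max(exp_sites / n_seqs, 1e-6), 1 - 1e-6)
    return probs, gamma, trace[-1], trace, Z_list


def discover_motif(
    flanks: Sequence[str],
    width: int = 11,
    n_starts: int = 50,
    seed: int = 0,
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
) -> DiscoveryResult:
    """Discover one ungapped motif in a set of flank sequences (ZOOPS EM).

    Seeds EM from the ``n_starts`` enumerated width-mers with the
    highest information (surprisal) under the background model, runs
    each to convergence, and returns the start with the best final
    objective.  The site list contains the best window of every
    sequence whose site posterior reaches 0.5 — with a ZOOPS model the
    motif may legitimately be absent from some sequences.

    The E-value is a closed-form normal-tail approximation: the number
    of enumerated starting words times the one-sided tail probability
    of the final information content under a background null (chi-square
    moments per column).  It is a rough significance guide, not
    comparable with MEME's E-values.
    """
    flanks = [f.upper() for f in flanks]
    usable = [f for f in flanks if len(f) >= width]
    if len(usable) < 2:
        raise ValueError(f"need >= 2 flanks of length >= {width}, got {len(usable)}")
    if any(len(f) < width for f in flanks):
        raise ValueError("all flanks must be at least motif width long")

    bg = _background_from(flanks) if background is None else np.asarray(background, float)
    encoded = [_encode(f) for f in flanks]
    # windows[i]: (m_i x width) matrix of base indices; windows containing N are dropped
    windows: list[np.ndarray] = []
    for enc in encoded:
        m = len(enc) - width + 1
        idx = np.arange(m)[:, None] + np.arange(width)[None, :]
        win = enc[idx]
        win = win[(win <= 3).all(axis=1)]
        if win.shape[0] == 0:
            raise ValueError("a flank has no N-free window of motif width")
        windows.append(win)

    # Candidate seed words: every distinct window, ranked by surprisal
    # under the background (rarest words first); ties broken by a
    # seed-shuffled deterministic order.
    all_words = np.vstack(windows)
    uniq = np.unique(all_words, axis=0)
    surprisal = -np.log2(bg)[uniq].sum(axis=1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    order = perm[np.argsort(-surprisal[perm], kind="stable")]
    seeds = uniq[order[: min(n_starts, len(uniq))]]
    n_enumerated = len(uniq)

    best = None
    for word in seeds:
        probs, gamma, obj, trace, Z_list = _zoops_em(windows, word, width, bg, pseudocount)
        if best is None or obj > best[2]:
            best = (probs, gamma, obj, trace, Z_list)
    probs, gamma, obj, trace, Z_list = best

    pwm = PositionWeightMatrix(probs=probs, background=bg, pseudocount=pseudocount)
    sites: list[tuple[int, int, str]] = []
    for i, Z in enumerate(Z_list):
        if Z.size and Z.max() >= 0.5:
            # map back to an offset in the original flank (N-free windows only)
            enc = encoded[i]
            m = len(enc) - width + 1
            idx = np.arange(m)[:, None] + np.arange(width)[None, :]
            keep = (enc[idx] <= 3).all(axis=1)
            offsets = np.flatnonzero(keep)
            j = int(offsets[int(np.argmax(Z))])
            sites.append((i, j, flanks[i][j : j + width]))

    # Normal-tail E-value approximation for the final information content
    n_sites = max(sum(Z.sum() for Z in Z_list), 1.0)
    ic = pwm.information_content
    ln2 = math.log(2)
    null_mean = 3 * width / (2 * n_sites * ln2)
    null_sd = math.sqrt(6 * width) / (2 * n_sites * ln2)
    z = (ic - null_mean) / null_sd
    evalue = float(n_enumerated * norm.sf(z))

    return DiscoveryResult(
        pwm=pwm, sites=sites, evalue=evalue, log_likelihood=obj, ll_trace=trace, gamma=gamma
    )


def train_motif_model(
    known_loci: Sequence[KnownLocusRecord],
    width: int = 11,
    seed: int = 0,
    n_starts: int = 50,
    pseudocount: float = 0.25,
) -> MotifModel:
    """Train the paired flank model from a known-locus panel.

    Discovery runs per repeat-unit category: all panel loci must share
    one repeat unit, otherwise the offending locus is named.  The 5' and
    3' PWMs are discovered independently on the upstream and downstream
    flank sets; each threshold defaults to the minimum log-odds score
    among that PWM's accepted training sites.
    """
    if not known_loci:
        raise ValueError("empty known-locus panel")
    unit = known_loci[0].unit
    for rec in known_loci:
        if rec.unit != unit:
            raise ValueError(
                f"mixed repeat units in panel: locus {rec.locus_id!r} has unit "
                f"{rec.unit} but the panel unit is {unit}; train per unit category"
            )
    res_5p = discover_motif(
        [r.upstream_flank for r in known_loci], width=width, n_starts=n_starts,
        seed=seed % (2**31), pseudocount=pseudocount,
    )
    res_3p = discover_motif(
        [r.downstream_flank for r in known_loci], width=width, n_starts=n_starts,
        seed=(seed + 1) % (2**31), pseudocount=pseudocount,
    )
    thr_5p = min(log_odds_score(res_5p.pwm, s) for _, _, s in res_5p.sites)
    thr_3p = min(log_odds_score(res_3p.pwm, s) for _, _, s in res_3p.sites)
    return MotifModel(
        pwm_5p=res_5p.pwm,
        pwm_3p=res_3p.pwm,
        threshold_5p=thr_5p,
        threshold_3p=thr_3p,
        evalue_5p=res_5p.evalue,
        evalue_3p=res_3p.evalue,
    )


# ---------------------------------------------------------------------------
# Serialisation: MEME minimal text format and JSON

def write_meme(model: MotifModel, path: str | Path, names: tuple[str, str] = ("flank_5p", "flank_3p")) -> None:
    """Write both PWMs in MEME minimal motif format."""
    bg = model.pwm_5p.background
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for name, pwm, ev in (
            (names[0], model.pwm_5p, model.evalue_5p),
            (names[1], model.pwm_3p, model.evalue_3p),
        ):
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 0 E= {ev:.3g}\n"
            )
            for j in range(pwm.width):
                fh.write(" " + " ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PositionWeightMatrix]:
    """Read PWMs back from MEME minimal format (columns re-normalised)."""
    pwms: list[PositionWeightMatrix] = []
    bg = np.full(4, 0.25)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[2 * k + 1]) for k in range(4)])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            probs = np.array(rows).T
            probs /= probs.sum(axis=0, keepdims=True)
            pwms.append(PositionWeightMatrix(probs=probs, background=bg))
            i += 1 + w
            continue
        i += 1
    return pwms


def model_to_json(model: MotifModel, path: str | Path) -> None:
    data = {
        "width": model.width,
        "background": model.pwm_5p.background.tolist(),
        "pwm_5p": model.pwm_5p.probs.tolist(),
        "pwm_3p": model.pwm_3p.probs.tolist(),
        "threshold_5p": model.threshold_5p,
        "threshold_3p": model.threshold_3p,
        "evalue_5p": model.evalue_5p,
        "evalue_3p": model.evalue_3p,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def model_from_json(path: str | Path) -> MotifModel:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    bg = np.array(data["background"])
    return MotifModel(
        pwm_5p=PositionWeightMatrix(np.array(data["pwm_5p"]), bg),
        pwm_3p=PositionWeightMatrix(np.array(data["pwm_3p"]), bg),
        threshold_5p=data["threshold_5p"],
        threshold_3p=data["threshold_3p"],
        evalue_5p=data.get("evalue_5p", float("nan")),
        evalue_3p=data.get("evalue_3p", float("nan")),
    )
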