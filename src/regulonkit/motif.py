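"""Peak post-processing, PWM models, exact p-values and motif machinery.

The scanner scores windows with integer-discretized log-odds (bits), so the
dynamic-programming null distribution used for p-values is *exact* for the
scores actually assigned — the same construction FIMO uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, Peak, PipelineConfig

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
_N_INDEX = 4

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    lut[ord("N")] = _N_INDEX
    out = lut[arr]
    if (out < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(out < 0)[0][:5]})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return out


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


def revcomp(seq: str) -> str:
    return decode(_COMPLEMENT_IDX[encode(seq)][::-1])


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A,C,G,T with a 0-order background."""

    probs: np.ndarray  # (4, width)
    background: np.ndarray  # (4,)
    pseudocount: float = 0.0
    n_sites: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probs must be a 4 x width matrix")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be a 4-vector summing to 1")
        if (bg <= 0).any():
            raise ValueError("background probabilities must be > 0")
        if self.pseudocount > 0 and (probs <= 0).any():
            raise ValueError("PWM with pseudocount > 0 must have all entries > 0")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-cell log2(prob / background), with -inf for zero cells."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    @property
    def information_content(self) -> float:
        """Mean per-column information content in bits (vs background)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = self.probs * np.log2(self.probs / self.background[:, None])
        return float(np.nansum(term) / self.width)

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
        )

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=self.probs[:, j]) for j in range(self.width)]
        return decode(np.array(cols))

    def consensus(self) -> str:
        return iupac_consensus(self)


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Estimate a PWM from aligned equal-length binding sites.

    probs[b, j] = (count(b, j) + pseudocount * background[b]) / (n + pseudocount)
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a PWM")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    counts = np.zeros((4, width))
    for s in sites:
        enc = encode(s.upper())
        if (enc == _N_INDEX).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        for j, b in enumerate(enc):
            counts[b, j] += 1
    n = len(sites)
    probs = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount, n_sites=n)


def iupac_consensus(pwm: PWM) -> str:
    """Call an IUPAC consensus letter per column.

    A single base is called when its probability is >= 0.5 and the runner-up
    is < 0.25.  Otherwise the smallest IUPAC set whose members each reach
    0.25 and jointly reach 0.75 is used, picking the highest-mass set among
    equals; unresolvable ties (e.g. a uniform column) give N.
    """
    letters = []
    for j in range(pwm.width):
        col = pwm.probs[:, j]
        order = np.argsort(col)[::-1]
        if col[order[0]] >= 0.5 and col[order[1]] < 0.25:
            letters.append(BASES[order[0]])
            continue
        best: str | None = None
        for size in (2, 3):
            candidates = []
            for members in _iupac_sets_of_size(size):
                p = [col[_BASE_INDEX[b]] for b in members]
                if all(x >= 0.25 for x in p) and sum(p) >= 0.75:
                    candidates.append((sum(p), members))
            if candidates:
                candidates.sort(key=lambda t: -t[0])
                if len(candidates) > 1 and math.isclose(
                    candidates[0][0], candidates[1][0], abs_tol=1e-12
                ):
                    best = "N"  # tie between equally good sets
                else:
                    best = IUPAC_CODES[frozenset(candidates[0][1])]
                break
        letters.append(best if best is not None else "N")
    return "".join(letters)


def _iupac_sets_of_size(size: int) -> list[str]:
    from itertools import combinations

    return ["".join(c) for c in combinations(BASES, size)]


# ---------------------------------------------------------------------------
# Peak post-processing
# ---------------------------------------------------------------------------

def prep_peaks(
    peaks: Sequence[Peak], cfg: PipelineConfig, chrom_lens: Mapping[str, int]
) -> list[GenomicInterval]:
    """Summit-center, trim to flank on each side and filter by fold enrichment.

    With the default flank of 100 each retained peak becomes a 201-bp
    fragment ``[summit - 100, summit + 101)`` (clipped at chromosome ends).
    The fold-enrichment boundary is inclusive: FE >= motif_fe_min is kept.
    """
    out: list[GenomicInterval] = []
    for p in peaks:
        chrom = p.interval.chrom
        chrom_len = chrom_lens[chrom]
        if p.summit >= chrom_len:
            raise ValueError(
                f"peak {p.name or '?'}: summit {p.summit} >= chromosome length {chrom_len}"
            )
        if p.fold_enrichment < cfg.motif_fe_min:
            continue
        lo = max(0, p.summit - cfg.summit_flank)
        hi = min(chrom_len, p.summit + cfg.summit_flank + 1)
        out.append(GenomicInterval(chrom, lo, hi, "."))
    return out


def shared_regions(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    cfg: PipelineConfig,
) -> tuple[list[tuple[GenomicInterval, GenomicInterval]], float]:
    """Pairs of regions overlapping by >= ``shared_min_overlap`` nt.

    Returns the overlapping (a, b) pairs and the fraction of ``set_a``
    regions that are shared with at least one region of ``set_b``.
    """
    if not set_a:
        raise ValueError("set_a is empty; shared fraction undefined")
    pairs = []
    shared_a = set()
    for i, a in enumerate(set_a):
        for b in set_b:
            if a.overlap(b) >= cfg.shared_min_overlap:
                pairs.append((a, b))
                shared_a.add(i)
    return pairs, len(shared_a) / len(set_a)


# ---------------------------------------------------------------------------
# Exact p-values
# ---------------------------------------------------------------------------

_MAX_TABLE_BINS = 20_000_000


class ScoreModel:
    """Integer-discretized log-odds scores and their exact null distribution.

    Per-cell log-odds (bits) are rounded to multiples of ``granularity``;
    window scores are sums of these integer bin scores, and the null
    distribution of the total under the 0-order background is computed by
    convolving the per-column score distributions.  p-values are therefore
    exact for the discretized scores.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be > 0")
        self.pwm = pwm
        self.granularity = granularity
        lod = pwm.log_odds
        if not np.isfinite(lod).all():
            # zero-probability cells: floor at a very negative finite score
            floor = np.log2(np.finfo(float).tiny)
            lod = np.where(np.isfinite(lod), lod, floor)
        self.bin_scores = np.round(lod / granularity).astype(np.int64)  # (4, w)
        self._build_table()

    def _build_table(self) -> None:
        bg = self.pwm.background
        min_total = int(self.bin_scores.min(axis=0).sum())
        max_total = int(self.bin_scores.max(axis=0).sum())
        span = max_total - min_total + 1
        if span > _MAX_TABLE_BINS:
            raise MemoryError(
                f"p-value table needs {span} bins; use a coarser granularity"
            )
        dist = np.zeros(span)
        offset = -min_total  # index of total score 0 shifted by column minima
        # running distribution over (partial total - running minimum)
        cur = np.array([1.0])
        cur_min = 0
        for j in range(self.pwm.width):
            col = self.bin_scores[:, j]
            cmin, cmax = int(col.min()), int(col.max())
            nxt = np.zeros(len(cur) + (cmax - cmin))
            for b in range(4):
                shift = int(col[b]) - cmin
                nxt[shift : shift + len(cur)] += bg[b] * cur
            cur = nxt
            cur_min += cmin
        assert cur_min == min_total and len(cur) == span
        dist[:] = cur
        total = dist.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise AssertionError(f"null distribution sums to {total}")
        # survival function: P(score >= s)
        sf = np.cumsum(dist[::-1])[::-1]
        self.min_total = min_total
        self.max_total = max_total
        self.pmf = dist
        self.sf = np.minimum(sf, 1.0)

    def pvalue(self, bin_score: int) -> float:
        """Exact P(score >= bin_score) under the background model."""
        if bin_score <= self.min_total:
            return 1.0
        if bin_score > self.max_total:
            return 0.0
        return float(self.sf[bin_score - self.min_total])

    def score_bits(self, bin_score: int) -> float:
        return bin_score * self.granularity

    def threshold_bin(self, p_max: float, inclusive: bool) -> int:
        """Smallest integer score whose p-value passes the threshold.

        ``inclusive=False`` requires p < p_max (stringent scan);
        ``inclusive=True`` requires p <= p_max (relaxed scan).
        Returns max_total + 1 when no score passes.
        """
        if p_max <= 0:
            raise ValueError("p_max must be > 0")
        ok = (self.sf <= p_max) if inclusive else (self.sf < p_max)
        idx = np.nonzero(ok)[0]
        if len(idx) == 0:
            return self.max_total + 1
        return int(idx[0]) + self.min_total


def pwm_pvalue_table(pwm: PWM, granularity: float = 1e-3) -> ScoreModel:
    """Exact null score distribution of ``pwm`` (see :class:`ScoreModel`)."""
    return ScoreModel(pwm, granularity)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A PWM match placed on the forward-strand coordinate frame."""

    interval: GenomicInterval
    strand: str
    score: float
    p_value: float
    matched_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("hit strand must be + or -")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if len(self.matched_seq) != len(self.interval):
            raise ValueError("matched_seq length must equal the hit interval length")


def _window_scores(enc: np.ndarray, bin_scores: np.ndarray) -> np.ndarray:
    """Total integer score of every window; windows containing N get -inf."""
    w = bin_scores.shape[1]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.zeros(0)
    idx = np.lib.stride_tricks.sliding_window_view(enc, w)  # (n_win, w)
    has_n = (idx == _N_INDEX).any(axis=1)
    safe = np.where(idx == _N_INDEX, 0, idx)
    scores = bin_scores[safe, np.arange(w)].sum(axis=1).astype(float)
    scores[has_n] = -np.inf
    return scores


def scan_sequences(
    pwm: PWM,
    sequences: Mapping[str, str],
    p_max: float,
    both_strands: bool = True,
    inclusive: bool = False,
    granularity: float = 1e-3,
    offsets: Mapping[str, int] | None = None,
    score_model: ScoreModel | None = None,
) -> list[MotifHit]:
    """Scan sequences for PWM matches passing an exact p-value threshold.

    ``inclusive=False`` keeps windows with p < p_max (stringent convention),
    ``inclusive=True`` keeps p <= p_max (relaxed convention).  Hits on the
    reverse strand are reported on the forward coordinate frame with
    ``strand='-'`` and ``matched_seq`` equal to the strand-matched motif.
    ``offsets`` maps each sequence key to its genomic start coordinate (for
    scanning extracted fragments).
    """
    model = score_model if score_model is not None else ScoreModel(pwm, granularity)
    thr = model.threshold_bin(p_max, inclusive)
    w = pwm.width
    rc_bins = model.bin_scores[::-1, ::-1]
    hits: list[MotifHit] = []
    for key, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < w:
            continue
        enc = encode(seq)
        base = 0 if offsets is None else offsets[key]
        fwd = _window_scores(enc, model.bin_scores)
        strand_scores = [("+", fwd)]
        if both_strands:
            strand_scores.append(("-", _window_scores(enc, rc_bins)))
        for strand, scores in strand_scores:
            for pos in np.nonzero(scores >= thr)[0]:
                bin_score = int(scores[pos])
                sub = seq[pos : pos + w]
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(key.split("@")[0], base + int(pos), base + int(pos) + w, "."),
                        strand=strand,
                        score=model.score_bits(bin_score),
                        p_value=model.pvalue(bin_score),
                        matched_seq=sub if strand == "+" else revcomp(sub),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


def scan_regions(
    pwm: PWM,
    genome: Mapping[str, str],
    regions: Sequence[GenomicInterval],
    p_max: float,
    both_strands: bool = True,
    inclusive: bool = False,
    granularity: float = 1e-3,
    score_model: ScoreModel | None = None,
) -> list[MotifHit]:
    """Scan extracted genomic regions; hit coordinates are genomic.

    Duplicate hits arising from overlapping regions are reported once.
    """
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for i, r in enumerate(regions):
        key = f"{r.chrom}@{i}"
        seqs[key] = genome[r.chrom][r.start : r.end]
        offsets[key] = r.start
    hits = scan_sequences(
        pwm,
        seqs,
        p_max,
        both_strands=both_strands,
        inclusive=inclusive,
        granularity=granularity,
        offsets=offsets,
        score_model=score_model,
    )
    unique: dict[tuple, MotifHit] = {}
    for h in hits:
        unique[(h.interval.chrom, h.interval.start, h.strand)] = h
    return sorted(
        unique.values(), key=lambda h: (h.interval.chrom, h.interval.start, h.strand)
    )


# ---------------------------------------------------------------------------
# EM motif discovery (ANR-style two-component mixture)
# ---------------------------------------------------------------------------

def em_discover(
    seqs: Sequence[str],
    width: int,
    restarts: int = 8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    background: np.ndarray | None = None,
    check_monotone: bool = True,
) -> tuple[PWM, list[str]]:
    """Discover one motif by EM over a motif/background window mixture.

    Every length-``width`` window of every sequence (both strands) is treated
    as an independent draw from a two-component mixture: motif (PWM) with
    prior gamma, or i.i.d. background.  The E-step computes per-window motif
    posteriors; the M-step re-estimates the PWM and gamma from them.  The
    best-likelihood solution over random restarts is returned together with
    the windows whose posterior exceeds 0.5.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    usable = [s.upper() for s in seqs if len(s) >= width]
    if not usable:
        raise ValueError(f"no sequence is at least {width} bp long")
    windows = _collect_windows(usable, width)
    if background is None:
        counts = np.bincount(np.concatenate([encode(s) for s in usable]), minlength=5)[:4]
        background = counts / counts.sum()
    bg = np.asarray(background, float)
    log_bg_win = np.log(bg)[windows].sum(axis=1)  # (n_win,)

    rng = np.random.default_rng(seed)
    best_ll = -np.inf
    best: tuple[np.ndarray, float] | None = None
    for _ in range(restarts):
        probs, gamma = _em_run(
            windows, log_bg_win, bg, width, rng, max_iter, tol, check_monotone
        )
        ll = _mixture_ll(windows, log_bg_win, probs, gamma)
        if ll > best_ll:
            best_ll = ll
            best = (probs, gamma)
    assert best is not None
    probs, gamma = best
    pwm = PWM(probs=probs, background=bg, pseudocount=0.0, n_sites=0)
    log_p = np.log(np.maximum(probs, 1e-300))
    log_motif = log_p[windows, np.arange(width)].sum(axis=1)
    post = _posteriors(log_motif, log_bg_win, gamma)
    sites = [decode(windows[i]) for i in np.nonzero(post > 0.5)[0]]
    return pwm, sites


def _collect_windows(seqs: Sequence[str], width: int) -> np.ndarray:
    chunks = []
    for s in seqs:
        enc = encode(s)
        if len(enc) < width:
            continue
        win = np.lib.stride_tricks.sliding_window_view(enc, width)
        ok = ~(win == _N_INDEX).any(axis=1)
        win = win[ok]
        chunks.append(win)
        rc = _COMPLEMENT_IDX[enc][::-1]
        win_rc = np.lib.stride_tricks.sliding_window_view(rc, width)
        ok = ~(win_rc == _N_INDEX).any(axis=1)
        chunks.append(win_rc[ok])
    if not chunks:
        raise ValueError("no N-free windows available")
    return np.concatenate(chunks).astype(np.int64)


def _posteriors(log_motif: np.ndarray, log_bg: np.ndarray, gamma: float) -> np.ndarray:
    a = np.log(gamma) + log_motif
    b = np.log1p(-gamma) + log_bg
    m = np.maximum(a, b)
    return np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))


def _mixture_ll(
    windows: np.ndarray, log_bg_win: np.ndarray, probs: np.ndarray, gamma: float
) -> float:
    log_p = np.log(np.maximum(probs, 1e-300))
    log_motif = log_p[windows, np.arange(windows.shape[1])].sum(axis=1)
    a = np.log(gamma) + log_motif
    b = np.log1p(-gamma) + log_bg_win
    m = np.maximum(a, b)
    return float((m + np.log(np.exp(a - m) + np.exp(b - m))).sum())


def _em_run(
    windows: np.ndarray,
    log_bg_win: np.ndarray,
    bg: np.ndarray,
    width: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    check_monotone: bool,
) -> tuple[np.ndarray, float]:
    n_win = windows.shape[0]
    # seed the PWM from one random window, smoothed toward background
    seed_win = windows[rng.integers(n_win)]
    probs = np.tile(bg[:, None] * 0.3, (1, width))
    probs[seed_win, np.arange(width)] += 0.7
    probs /= probs.sum(axis=0, keepdims=True)
    gamma = 0.01
    prior = 0.1 * bg[:, None]  # Dirichlet smoothing of the M-step

    def _penalized(probs_: np.ndarray, gamma_: float) -> float:
        # MAP objective: mixture LL + Dirichlet prior term.  This (not the
        # raw LL) is what the smoothed M-step increases monotonically.
        prior_term = float((prior * np.log(np.maximum(probs_, 1e-300))).sum())
        return _mixture_ll(windows, log_bg_win, probs_, gamma_) + prior_term

    prev_obj = -np.inf
    onehot = np.eye(4)[windows]  # (n_win, width, 4)
    for _ in range(max_iter):
        log_p = np.log(np.maximum(probs, 1e-300))
        log_motif = log_p[windows, np.arange(width)].sum(axis=1)
        post = _posteriors(log_motif, log_bg_win, gamma)
        obj = _penalized(probs, gamma)
        if check_monotone and obj < prev_obj - 1e-9 * max(1.0, abs(prev_obj)):
            raise AssertionError(f"EM objective decreased: {prev_obj} -> {obj}")
        if obj - prev_obj < tol and np.isfinite(prev_obj):
            break
        prev_obj = obj
        weight = post.sum()
        counts = np.einsum("n,nwb->bw", post, onehot) + prior
        probs = counts / counts.sum(axis=0, keepdims=True)
        gamma = min(max(weight / n_win, 1e-6), 0.5)
    return probs, gamma


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(pwm: PWM, path: str | Path, name: str = "MOTIF_1") -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, pwm.background))
            + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(pwm.n_sites, 1)} E= 0\n"
        )
        for j in range(pwm.width):
            fh.write(" ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)) + "\n")


def read_meme(path: str | Path) -> PWM:
    lines = Path(path).read_text().splitlines()
    bg = UNIFORM_BACKGROUND.copy()
    rows: list[list[float]] = []
    n_sites = 0
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            bg /= bg.sum()  # undo 6-decimal rounding
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            import re as _re

            m = _re.search(r"w=\s*(\d+)", line)
            n = _re.search(r"nsites=\s*(\d+)", line)
            if m is None:
                raise ValueError(f"{path}: malformed matrix header {line!r}")
            width = int(m.group(1))
            n_sites = int(n.group(1)) if n else 0
            for k in range(width):
                rows.append([float(x) for x in lines[i + 1 + k].split()])
            i += 1 + width
            continue
        i += 1
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    probs = np.array(rows).T
    probs /= probs.sum(axis=0, keepdims=True)
    return PWM(probs=probs, background=bg, n_sites=n_sites)


def hits_to_bed6(hits: Iterable[MotifHit]):
    """Hits as BED6 triples with score = -log10(p)."""
    out = []
    for h in hits:
        iv = GenomicInterval(h.interval.chrom, h.interval.start, h.interval.end, h.strand)
        out.append((iv, h.matched_seq, -math.log10(h.p_value)))
    return out
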