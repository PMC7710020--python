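"""PWM log-odds scanning against a Markov background with empirical FDR.

Scoring uses log2(p_motif / p_background) per column with background
mononucleotide frequencies; the order-k Markov model (default k=2,
trained on the genome with a pseudocount) is used to generate null
sequences from which a motif-score threshold is calibrated at a target
empirical FDR: the smallest score for which the null-sequence hit rate
divided by the query-sequence hit rate drops below the target.
Windows containing N score -inf and can never be hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genome, BASE_CODES
from .synth import MotifModel, _revcomp


def encode(seq: str) -> np.ndarray:
    """Sequence to uint8 codes (A0 C1 G2 T3, N/other 4)."""
    return BASE_CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return np.frombuffer(b"ACGTN", dtype=np.uint8)[codes].tobytes().decode()


# --------------------------------------------------------------------------
# Markov background


@dataclass
class MarkovBackground:
    """Order-k Markov sequence model with conditional base probabilities."""

    order: int
    conditional: np.ndarray   # (4^k, 4) rows sum to 1
    initial: np.ndarray       # (4^k,) distribution of the first k-mer
    mono: np.ndarray          # (4,) stationary mononucleotide frequencies
    training_bases: int = 0

    def context_index(self, codes: np.ndarray) -> np.ndarray:
        """Index of each k-mer context ending at position i (vectorized)."""
        k = self.order
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + codes[j: len(codes) - k + 1 + j]
        return idx

    def log_likelihood(self, seq: str) -> float:
        """log2 probability of a sequence under the model."""
        codes = encode(seq)
        if np.any(codes > 3):
            return -np.inf
        k = self.order
        if len(codes) <= k:
            # marginalize the initial k-mer distribution
            p = self.initial.reshape((4,) * k) if k else np.array(1.0)
            for axis in range(k - len(codes)):
                p = p.sum(axis=-1)
            for c in codes:
                p = p[c] if p.ndim else p
            return float(np.log2(p))
        ctx = self.context_index(codes[:-1])
        nxt = codes[k:]
        ll = np.log2(self.initial[self.context_index(codes[:k])[0]])
        ll += np.log2(self.conditional[ctx, nxt]).sum()
        return float(ll)


def train_background(genome: Genome, order: int = 2,
                     pseudocount: float = 1.0) -> MarkovBackground:
    """Estimate conditional probabilities from (k+1)-mer counts; windows
    containing N are skipped."""
    if order < 0:
        raise ValueError("order must be >= 0")
    k = order
    n_ctx = 4 ** k
    counts = np.zeros((n_ctx, 4), dtype=np.int64)
    init_counts = np.zeros(n_ctx, dtype=np.int64)
    mono = np.zeros(4, dtype=np.int64)
    total = 0
    for chrom in genome.chrom_names:
        codes = genome.codes(chrom)
        total += len(codes)
        mono += np.bincount(codes[codes < 4], minlength=4)
        if len(codes) < k + 1:
            continue
        valid = codes < 4
        if k == 0:
            counts[0] += np.bincount(codes[valid], minlength=4)
            continue
        ctx = np.zeros(len(codes) - k, dtype=np.int64)
        ok = np.ones(len(codes) - k, dtype=bool)
        for j in range(k):
            ctx = ctx * 4 + codes[j: len(codes) - k + j]
            ok &= valid[j: len(codes) - k + j]
        nxt = codes[k:]
        ok &= valid[k:]
        flat = ctx[ok] * 4 + nxt[ok]
        counts += np.bincount(flat, minlength=n_ctx * 4).reshape(n_ctx, 4)
        init_counts += np.bincount(ctx[ok], minlength=n_ctx)
    if genome.total_length <= 4 ** (k + 1):
        raise ValueError("genome too short to train this model order")
    cond = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    init = (init_counts + pseudocount) / (init_counts + pseudocount).sum()
    monof = mono / mono.sum() if mono.sum() else np.full(4, 0.25)
    return MarkovBackground(order=k, conditional=cond, initial=init,
                            mono=monof, training_bases=total)


def sample_sequences(bg: MarkovBackground, n: int, length: int = 100,
                     seed: int = 0) -> list[str]:
    """n i.i.d. sequences of the given length from the Markov model."""
    return [decode(row) for row in sample_codes(bg, n, length, seed)]


def sample_codes(bg: MarkovBackground, n: int, length: int = 100,
                 seed: int = 0) -> np.ndarray:
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = bg.order
    out = np.empty((n, length), dtype=np.uint8)
    if k == 0:
        cdf = np.cumsum(bg.conditional[0])
        u = rng.random((n, length))
        return np.searchsorted(cdf, u).astype(np.uint8)
    # draw the initial k-mer from the initial distribution
    init_cdf = np.cumsum(bg.initial)
    start = np.searchsorted(init_cdf, rng.random(n))
    for j in range(min(k, length) - 1, -1, -1):
        out[:, j] = start % 4
        start //= 4
    if length <= k:
        return out[:, :length]
    cond_cdf = np.cumsum(bg.conditional, axis=1)
    ctx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        ctx = ctx * 4 + out[:, j]
    mod = 4 ** (k - 1)
    for pos in range(k, length):
        u = rng.random(n)
        rows = cond_cdf[ctx]
        nxt = (u[:, None] > rows).sum(axis=1).astype(np.uint8)
        out[:, pos] = nxt
        ctx = (ctx % mod) * 4 + nxt
    return out


# --------------------------------------------------------------------------
# scoring


@dataclass
class ScoredMotif:
    """A motif with its log-odds matrix and calibrated score threshold."""

    motif: MotifModel
    log_odds: np.ndarray            # (width, 5); column 4 (N) is -inf
    threshold: float | None = None
    calibration: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.motif.width

    @classmethod
    def from_motif(cls, motif: MotifModel, bg: MarkovBackground,
                   pseudocount: float = 0.01) -> "ScoredMotif":
        p = motif.matrix + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        lo = np.full((motif.width, 5), -np.inf)
        lo[:, :4] = np.log2(p) - np.log2(bg.mono)[None, :]
        return cls(motif=motif, log_odds=lo)

    @property
    def rc_log_odds(self) -> np.ndarray:
        rc = self.log_odds[::-1, [3, 2, 1, 0, 4]]
        return rc


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of all windows along axis -1 (works on 1-D or 2-D input)."""
    w = matrix.shape[0]
    L = codes.shape[-1]
    if L < w:
        shape = codes.shape[:-1] + (0,)
        return np.empty(shape)
    n_win = L - w + 1
    scores = np.zeros(codes.shape[:-1] + (n_win,))
    for j in range(w):
        scores += matrix[j, codes[..., j: j + n_win]]
    return scores


def scan(sequence: str, scored: ScoredMotif, both_strands: bool = True):
    """Score every window of the sequence on one or both strands.

    Returns (positions, strands, scores): window start coordinates on
    the forward strand, '+'/'-' labels and log-odds scores.  A '-' hit
    at position i means the reverse complement of sequence[i:i+w]
    matches the motif.
    """
    codes = encode(sequence)
    fwd = _window_scores(codes, scored.log_odds)
    pos = np.arange(len(fwd))
    if not both_strands:
        return pos, np.full(len(fwd), "+"), fwd
    rev = _window_scores(codes, scored.rc_log_odds)
    positions = np.concatenate([pos, pos])
    strands = np.array(["+"] * len(fwd) + ["-"] * len(rev))
    scores = np.concatenate([fwd, rev])
    return positions, strands, scores


def max_scores(seq_codes: np.ndarray, scored: ScoredMotif,
               both_strands: bool = True) -> np.ndarray:
    """Per-sequence best window score for a (n, L) code matrix."""
    with np.errstate(invalid="ignore"):
        best = _window_scores(seq_codes, scored.log_odds).max(axis=-1)
        if both_strands:
            rbest = _window_scores(seq_codes, scored.rc_log_odds).max(axis=-1)
            best = np.maximum(best, rbest)
    return best


def embed_motif_instances(motif: MotifModel, bg: MarkovBackground, n: int,
                          length: int = 100, seed: int = 0,
                          sample: bool = False) -> np.ndarray:
    """Background sequences with one motif instance planted at a random
    position in each; the calibration query of the empirical-FDR
    procedure.  ``sample=True`` draws instances from the probability
    matrix instead of planting the consensus."""
    mat = sample_codes(bg, n, length, seed)
    rng = np.random.default_rng((seed + 104729) % 2**31)
    w = motif.width
    starts = rng.integers(0, length - w + 1, size=n)
    cons = encode(motif.consensus)
    for i in range(n):
        inst = encode(motif.sample(rng)) if sample else cons
        mat[i, starts[i]: starts[i] + w] = inst
    return mat


class NoDiscriminativeThreshold(Exception):
    """The target empirical FDR is unattainable for these sequence sets."""


def calibrate_threshold(scored: ScoredMotif, query_seqs, null_seqs,
                        fdr_target: float = 0.1,
                        method: str = "ratio") -> float:
    """Calibrate the motif score threshold at a target empirical FDR.

    ``ratio`` (default): using per-sequence max scores, the threshold is
    the smallest s with null_rate(s)/query_rate(s) <= fdr_target.
    ``null_quantile``: the (1 - fdr_target) quantile of the null max
    scores.  Raises NoDiscriminativeThreshold when no score achieves the
    target.  Sets and returns ``scored.threshold``.
    """
    if len(query_seqs) == 0 or len(null_seqs) == 0:
        raise ValueError("query and null sequence sets must be non-empty")
    qmax = _as_max_scores(query_seqs, scored)
    nmax = _as_max_scores(null_seqs, scored)
    if method == "null_quantile":
        thr = float(np.quantile(nmax, 1.0 - fdr_target))
        scored.threshold = thr
        scored.calibration = {"method": method, "fdr_target": fdr_target,
                              "n_null": len(nmax), "n_query": len(qmax)}
        return thr
    if method != "ratio":
        raise ValueError(f"unknown method {method!r}")
    candidates = np.unique(np.concatenate([qmax, nmax]))
    candidates = candidates[np.isfinite(candidates)]
    nq, nn = len(qmax), len(nmax)
    qs = np.sort(qmax)
    ns = np.sort(nmax)
    # hit rates at threshold s: fraction of sequences with max >= s
    q_rate = (nq - np.searchsorted(qs, candidates, side="left")) / nq
    n_rate = (nn - np.searchsorted(ns, candidates, side="left")) / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(q_rate > 0, n_rate / q_rate, np.inf)
    ok = np.flatnonzero(fdr <= fdr_target)
    if len(ok) == 0:
        raise NoDiscriminativeThreshold(
            f"no score threshold achieves FDR <= {fdr_target}")
    thr = float(candidates[ok[0]])
    scored.threshold = thr
    scored.calibration = {"method": "ratio", "fdr_target": fdr_target,
                          "n_null": nn, "n_query": nq,
                          "realized_fdr": float(fdr[ok[0]])}
    return thr


def _as_max_scores(seqs, scored: ScoredMotif) -> np.ndarray:
    if isinstance(seqs, np.ndarray) and seqs.ndim == 2:
        return max_scores(seqs, scored)
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        mat = np.stack([encode(s) for s in seqs])
        return max_scores(mat, scored)
    return np.array([max_scores(encode(s)[None, :], scored)[0] for s in seqs])


# --------------------------------------------------------------------------
# peak-set hit calling and over-representation


def peaks_with_hits(peaks: pd.DataFrame, genome: Genome, scored: ScoredMotif,
                    within: int = 50) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag peaks with a motif hit starting within +-``within`` bp of the
    peak point; also return the individual hits (offset of motif start
    relative to the peak point, strand, score)."""
    if scored.threshold is None:
        raise ValueError("motif threshold not calibrated")
    w = scored.width
    flags = np.zeros(len(peaks), dtype=bool)
    hit_rows = []
    for i, (_, pk) in enumerate(peaks.iterrows()):
        start = int(pk.point) - within
        seq = genome.fetch(pk.chrom, start, int(pk.point) + within + w)
        clip_offset = max(0, -start)  # bp clipped at the chromosome start
        pos, strands, scores = scan(seq, scored)
        above = scores >= scored.threshold
        if not np.any(above):
            continue
        flags[i] = True
        offs = pos[above] + start + clip_offset - int(pk.point)
        for off, strand, score in zip(offs, strands[above], scores[above]):
            hit_rows.append({"peak": i, "offset": int(off), "strand": strand,
                             "score": float(score)})
    hits = pd.DataFrame(hit_rows, columns=["peak", "offset", "strand", "score"])
    return flags, hits


def overrepresentation(query_hits: int, query_total: int, genome: Genome,
                       scored: ScoredMotif, n_background: int = 10_000,
                       length: int = 100, seed: int = 0) -> dict:
    """Motif hit-rate ratio of a peak set vs random genomic windows, with
    a Fisher exact p on the 2x2 hit table."""
    if scored.threshold is None:
        raise ValueError("motif threshold not calibrated")
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    usable = lens - length
    if np.all(usable <= 0):
        raise ValueError("genome shorter than the background window length")
    which = rng.choice(len(chroms), size=n_background, p=usable / usable.sum())
    starts = (rng.random(n_background) * usable[which]).astype(np.int64)
    mat = np.stack([encode(genome.fetch(chroms[c], s, s + length))
                    for c, s in zip(which, starts)])
    bg_hits = int(np.sum(max_scores(mat, scored) >= scored.threshold))
    q_rate = query_hits / query_total if query_total else 0.0
    b_rate = bg_hits / n_background
    table = [[query_hits, query_total - query_hits],
             [bg_hits, n_background - bg_hits]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    ratio = np.inf if b_rate == 0 and q_rate > 0 else (
        q_rate / b_rate if b_rate else np.nan)
    return {"rate_ratio": ratio, "p": p, "query_rate": q_rate,
            "background_rate": b_rate, "n_background": n_background}


def hit_position_histogram(hits: pd.DataFrame, half_window: int = 250,
                           bin: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hit offsets over [-half_window, half_window)."""
    edges = np.arange(-half_window, half_window + bin, bin)
    counts, _ = np.histogram(hits["offset"].to_numpy() if len(hits) else [],
                             bins=edges)
    return counts, edges
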