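"""Promoter scanning with position frequency matrices.

Sequences are scored with log-ratio weight matrices derived from PFMs
against an order-``m`` Markov background estimated from the scanned
promoter set itself (strand-pooled). Site p-values are exact under the
background model: the full distribution of the discretized window score
is computed by dynamic programming over (position, Markov context,
score), and hits are called at ``pvalue <= p_threshold``.

Scoring convention
------------------
Window scores use position-independent stationary-background weights
``ln f'(i, b) - ln stationary(b)``; the Markov chain (order ``m``)
governs letter generation inside the p-value DP. Scores are floored to
multiples of ``granularity`` both in the DP and at scan time, so p-value
lookups are exact for every scored window and conservative with respect
to the continuous score (flooring can only inflate a reported p-value).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .formats_io import SequenceSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0, C=1, G=2, T=3, other=-1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PFM:
    """Position frequency matrix for one TF motif.

    ``probs`` has shape (w, 4) in A, C, G, T order; every row sums to 1.
    """

    tf_id: str
    motif_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PFM {self.motif_id}: need a (w, 4) matrix with w >= 1")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"PFM {self.motif_id}: probabilities outside [0, 1]")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"PFM {self.motif_id}: rows must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


@dataclasses.dataclass(frozen=True)
class MarkovBackground:
    """Order-``m`` Markov model of the background sequence.

    transition[c, b] is P(next base = b | preceding m bases encode to c);
    context_probs[c] is the marginal probability of context c, and
    stationary is the marginal base distribution. Context codes treat the
    first (oldest) base as the most significant base-4 digit.
    """

    order: int
    transition: np.ndarray  # (4**m, 4)
    stationary: np.ndarray  # (4,)
    context_probs: np.ndarray  # (4**m,)

    def __post_init__(self) -> None:
        n_ctx = 4**self.order
        if self.transition.shape != (n_ctx, 4):
            raise ValueError("transition matrix shape inconsistent with order")
        rows = self.transition.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("each context's conditional probabilities must sum to 1")


@dataclasses.dataclass(frozen=True)
class WeightMatrix:
    """Log-ratio scoring matrix: ln f'(i, b) - ln stationary(b)."""

    tf_id: str
    motif_id: str
    weights: np.ndarray  # (w, 4)
    pseudo_frequency: float = 0.001

    @property
    def width(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the discretized window score under the background.

    Integer scores are floored weights in units of ``granularity``;
    ``probs[k]`` is P(total integer score == min_score + k) and ``sf`` the
    corresponding survival function P(score >= s).
    """

    granularity: float
    iweights: np.ndarray  # (w, 4) int64, floored weights
    min_score: int
    probs: np.ndarray
    sf: np.ndarray

    @property
    def support(self) -> np.ndarray:
        """Achievable integer scores (positive probability)."""
        return self.min_score + np.nonzero(self.probs > 0)[0]

    def pvalue_int(self, score: int | np.ndarray):
        """P(background integer score >= ``score``)."""
        idx = np.clip(np.asarray(score) - self.min_score, 0, len(self.sf) - 1)
        return self.sf[idx]

    def score_threshold(self, p_threshold: float) -> int | None:
        """Smallest integer score with p-value <= ``p_threshold`` (None if unreachable)."""
        ok = np.nonzero(self.sf <= p_threshold)[0]
        if len(ok) == 0:
            return None
        return int(self.min_score + ok[0])


@dataclasses.dataclass(frozen=True)
class BindingSiteHit:
    """One predicted binding site in a promoter, forward coordinates, 1-based."""

    tf_id: str
    motif_id: str
    gene_id: str
    start: int
    strand: str
    matched_word: str
    score: float
    pvalue: float


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def _iter_sequences(sequences) -> Iterable[str]:
    if hasattr(sequences, "records"):
        return list(sequences.records.values())
    if isinstance(sequences, Mapping):
        return list(sequences.values())
    return list(sequences)


def build_markov_background(
    sequences,
    m: int,
    pseudo_count: float = 1.0,
    pool_strands: bool = True,
) -> MarkovBackground:
    """Estimate an order-``m`` Markov background from nucleotide sequences.

    Counts of (context, base) pairs are pooled over the sequences and, if
    ``pool_strands``, their reverse complements; windows touching an N are
    skipped. ``pseudo_count`` is added to every transition cell so all
    probabilities stay positive.
    """
    if m < 0:
        raise ValueError("Markov order m must be >= 0")
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    seqs = _iter_sequences(sequences)
    if sum(len(s) for s in seqs) == 0:
        raise ValueError("background estimation requires non-empty sequences")
    if pool_strands:
        seqs = seqs + [reverse_complement(s) for s in seqs]

    n_ctx = 4**m
    trans_counts = np.zeros((n_ctx, 4), dtype=np.int64)
    base_counts = np.zeros(4, dtype=np.int64)
    powers = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64) if m > 0 else None

    for seq in seqs:
        enc = encode(seq)
        valid = enc >= 0
        base_counts += np.bincount(enc[valid], minlength=4)
        if len(enc) < m + 1:
            continue
        k = m + 1
        n_win = len(enc) - m
        # window validity: all k positions non-N
        ok = np.ones(n_win, dtype=bool)
        for off in range(k):
            ok &= valid[off : off + n_win]
        if m == 0:
            codes = np.zeros(n_win, dtype=np.int64)
        else:
            codes = np.zeros(n_win, dtype=np.int64)
            for off in range(m):
                codes += enc[off : off + n_win].astype(np.int64) * powers[off]
        nxt = enc[m : m + n_win].astype(np.int64)
        flat = codes[ok] * 4 + nxt[ok]
        trans_counts += np.bincount(flat, minlength=n_ctx * 4).reshape(n_ctx, 4)

    ctx_counts = trans_counts.sum(axis=1)
    denom = ctx_counts + 4.0 * pseudo_count
    transition = np.empty((n_ctx, 4), dtype=float)
    zero = denom == 0
    transition[zero] = 0.25  # unobserved context with no pseudo-count: uniform
    nz = ~zero
    transition[nz] = (trans_counts[nz] + pseudo_count) / denom[nz, None]

    total_ctx = ctx_counts.sum()
    ctx_denom = total_ctx + n_ctx * pseudo_count
    if ctx_denom == 0:
        context_probs = np.full(n_ctx, 1.0 / n_ctx)
    else:
        context_probs = (ctx_counts + pseudo_count) / ctx_denom

    total_bases = base_counts.sum()
    stat_denom = total_bases + 4.0 * pseudo_count
    if stat_denom == 0:
        stationary = np.full(4, 0.25)
    else:
        stationary = (base_counts + pseudo_count) / stat_denom

    return MarkovBackground(
        order=m,
        transition=transition,
        stationary=stationary,
        context_probs=context_probs,
    )


# ---------------------------------------------------------------------------
# weight matrix and score distribution
# ---------------------------------------------------------------------------


def pfm_to_weight_matrix(
    pfm: PFM, background: MarkovBackground, pseudo_frequency: float = 0.001
) -> WeightMatrix:
    """Convert a PFM to log-ratio weights against the stationary background.

    Corrected frequencies f'(i, b) = (f(i, b) + pf) / (1 + 4 pf); weights
    are ln f'(i, b) - ln stationary(b), finite for pf > 0.
    """
    if pseudo_frequency <= 0:
        raise ValueError("pseudo_frequency must be > 0")
    corrected = (pfm.probs + pseudo_frequency) / (1.0 + 4.0 * pseudo_frequency)
    weights = np.log(corrected) - np.log(background.stationary)[None, :]
    return WeightMatrix(
        tf_id=pfm.tf_id,
        motif_id=pfm.motif_id,
        weights=weights,
        pseudo_frequency=pseudo_frequency,
    )


def _floored_weights(wm: WeightMatrix, granularity: float) -> np.ndarray:
    return np.floor(wm.weights / granularity).astype(np.int64)


def score_pvalue_table(
    wm: WeightMatrix, background: MarkovBackground, granularity: float = 1e-3
) -> ScoreDistribution:
    """Exact distribution of the discretized window score under the background.

    Weights are floored to integer multiples of ``granularity`` (conservative:
    reported p-values can only be inflated, by at most w*granularity in score
    units). For order m > 0 the first m letters of the window follow the
    background's context marginal and subsequent letters the Markov chain.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    iw = _floored_weights(wm, granularity)
    w = iw.shape[0]
    m = background.order
    n_ctx = 4**m

    if w <= m:
        # marginalize the context distribution over its first w letters
        marg = background.context_probs.reshape((4,) * m)
        marg = marg.sum(axis=tuple(range(w, m))) if w < m else marg
        word_probs = marg.reshape(-1)
        scores = np.zeros(4**w, dtype=np.int64)
        for i in range(w):
            digit = (np.arange(4**w) // 4 ** (w - 1 - i)) % 4
            scores += iw[i, digit]
        smin, smax = int(scores.min()), int(scores.max())
        probs = np.zeros(smax - smin + 1)
        np.add.at(probs, scores - smin, word_probs)
    else:
        # initialize on full contexts (first m letters)
        digits = [(np.arange(n_ctx) // 4 ** (m - 1 - i)) % 4 for i in range(m)]
        init_scores = np.zeros(n_ctx, dtype=np.int64)
        for i in range(m):
            init_scores += iw[i, digits[i]]
        if m == 0:
            cur_min = 0
            dp = np.ones((1, 1))
        else:
            cur_min = int(init_scores.min())
            width = int(init_scores.max()) - cur_min + 1
            dp = np.zeros((n_ctx, width))
            dp[np.arange(n_ctx), init_scores - cur_min] = background.context_probs
        for i in range(m, w):
            row = iw[i]
            rmin, rmax = int(row.min()), int(row.max())
            cur_width = dp.shape[1]
            new = np.zeros((n_ctx, cur_width + rmax - rmin))
            for c in range(n_ctx):
                col = dp[c]
                if not col.any():
                    continue
                for b in range(4):
                    p = background.transition[c, b]
                    if p == 0:
                        continue
                    off = int(row[b]) - rmin
                    new[(c * 4 + b) % n_ctx, off : off + cur_width] += col * p
            dp = new
            cur_min += rmin
        probs = dp.sum(axis=0)
        smin = cur_min

    # trim zero tails so support bounds are tight
    nz = np.nonzero(probs > 0)[0]
    probs = probs[nz[0] : nz[-1] + 1]
    smin = int(smin + nz[0])
    sf = np.cumsum(probs[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return ScoreDistribution(
        granularity=granularity, iweights=iw, min_score=smin, probs=probs, sf=sf
    )


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _window_scores(enc: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window and a validity mask (no N inside the window)."""
    w = matrix.shape[0]
    n = len(enc) - w + 1
    valid = np.ones(n, dtype=bool)
    safe = np.where(enc >= 0, enc, 0)
    scores = np.zeros(n, dtype=matrix.dtype)
    for i in range(w):
        scores += matrix[i, safe[i : i + n]]
        valid &= enc[i : i + n] >= 0
    return scores, valid


def scan_sequence(
    seq: str,
    wm: WeightMatrix,
    background: MarkovBackground,
    dist: ScoreDistribution,
    p_threshold: float = 1e-5,
    strands: str = "both",
    gene_id: str = "",
) -> list[BindingSiteHit]:
    """Report binding sites of one motif in one sequence.

    Every length-w window on the requested strand(s) is scored; windows
    containing N are skipped; a hit is reported iff its discretized-score
    p-value is <= ``p_threshold``. Positions are 1-based on the forward
    strand (leftmost window coordinate) with a strand flag; minus-strand
    windows are scored on their reverse complement.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    seq = seq.upper()
    w = wm.width
    if len(seq) < w:
        return []
    thr = dist.score_threshold(p_threshold)
    if thr is None:
        return []
    enc = encode(seq)
    hits: list[BindingSiteHit] = []

    def collect(matrix_int: np.ndarray, matrix_f: np.ndarray, strand: str) -> None:
        iscores, valid = _window_scores(enc, matrix_int)
        idx = np.nonzero(valid & (iscores >= thr))[0]
        if len(idx) == 0:
            return
        fscores, _ = _window_scores(enc, matrix_f)
        pvals = dist.pvalue_int(iscores[idx])
        for j, p in zip(idx, np.atleast_1d(pvals)):
            word = seq[j : j + w]
            if strand == "-":
                word = reverse_complement(word)
            hits.append(
                BindingSiteHit(
                    tf_id=wm.tf_id,
                    motif_id=wm.motif_id,
                    gene_id=gene_id,
                    start=int(j) + 1,
                    strand=strand,
                    matched_word=word,
                    score=float(fscores[j]),
                    pvalue=float(p),
                )
            )

    collect(dist.iweights, wm.weights, "+")
    if strands == "both":
        # scoring the reverse complement of each window == scoring the forward
        # window with the reversed-complemented matrix
        iw_rc = dist.iweights[::-1, ::-1]
        w_rc = wm.weights[::-1, ::-1]
        collect(iw_rc, w_rc, "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(
    promoters,
    pfms: list[PFM],
    m: int = 2,
    p_threshold: float = 1e-5,
    pseudo_frequency: float = 0.001,
    granularity: float = 1e-3,
    strands: str = "both",
    background: MarkovBackground | None = None,
) -> list[BindingSiteHit]:
    """Scan every promoter with every PFM against a shared background.

    The background is estimated once from the promoter set itself
    (strand-pooled) unless one is supplied.
    """
    if not pfms:
        logger.warning("scan_promoters called with zero PFMs; returning no hits")
        return []
    if background is None:
        background = build_markov_background(promoters, m=m)
    records = promoters.records if hasattr(promoters, "records") else dict(promoters)
    hits: list[BindingSiteHit] = []
    for pfm in pfms:
        wm = pfm_to_weight_matrix(pfm, background, pseudo_frequency=pseudo_frequency)
        dist = score_pvalue_table(wm, background, granularity=granularity)
        for gene_id, seq in records.items():
            hits.extend(
                scan_sequence(
                    seq,
                    wm,
                    background,
                    dist,
                    p_threshold=p_threshold,
                    strands=strands,
                    gene_id=gene_id,
                )
            )
    return hits
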