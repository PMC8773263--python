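"""No-replicate differential expression calling.

Gene-level low-count filtering, TMM (trimmed mean of M values)
normalization, and a differential-expression probability computed from
simulated technical replicates: for each of the two conditions, ``nss``
replicates are drawn as multinomial subsamples of the observed library
at roughly ``pnr`` of its depth; the per-gene signal (|M|, D) between
the condition means is compared against the pooled within-condition
noise (|M|, D) cloud, and q is the fraction of noise points strictly
dominated by the signal. Genes with q >= 0.9 are called differentially
expressed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .formats_io import CountTable


@dataclasses.dataclass(frozen=True)
class NormalizationResult:
    """Per-sample TMM scaling factors (geometric mean 1) and effective sizes."""

    factors: dict[str, float]
    effective_library_size: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()))
        if np.any(vals <= 0):
            raise ValueError("TMM factors must be positive")


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Technical-replicate simulation settings.

    Defaults are the published values: pnr = 0.2 (fraction of the library
    depth per simulated replicate), nss = 10 replicates per condition,
    v = 0.02 (half-width of the uniform jitter on replicate totals).
    """

    pnr: float = 0.2
    nss: int = 10
    v: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pnr <= 1):
            raise ValueError("pnr must be in (0, 1]")
        if self.nss < 2:
            raise ValueError("nss must be >= 2 (noise needs replicate pairs)")
        if not (0 <= self.v < self.pnr):
            raise ValueError("v must satisfy 0 <= v < pnr")


@dataclasses.dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression summary (condition 1 vs condition 2)."""

    gene_id: str
    mean_cond1: float
    mean_cond2: float
    M: float  # log2(mean_cond1 / mean_cond2)
    D: float  # |mean_cond1 - mean_cond2|
    q: float
    direction: str  # up / down / none


def filter_low_counts(counts: CountTable, min_reads: int = 5) -> CountTable:
    """Drop genes whose maximum count across samples is below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = counts.counts.max(axis=1) >= min_reads
    return CountTable(counts=counts.counts.loc[keep].copy(), conditions=dict(counts.conditions))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float
) -> float:
    """TMM factor of one sample against the reference (log2 scale returned as 2**x)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return 1.0
    o, r = obs[both].astype(float), ref[both].astype(float)
    M = np.log2((o / n_obs) / (r / n_ref))
    A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_M = np.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = np.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM, rA = rankdata(M), rankdata(A)
    keep = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if not keep.any():
        return 1.0
    # inverse asymptotic (binomial) variance weights
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2.0**f)


def tmm_normalize(
    counts: CountTable, trim_M: float = 0.30, trim_A: float = 0.05
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples. M and A statistics over genes
    positive in both libraries are doubly trimmed (``trim_M`` on M,
    ``trim_A`` on A) and averaged with inverse binomial-variance weights;
    the resulting factors are rescaled to geometric mean 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    samples = counts.samples
    if len(samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = samples[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    f75 = np.array([np.quantile(mat[:, k], 0.75) / lib[k] for k in range(len(samples))])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if k == ref_idx
            else _tmm_pair(mat[:, k], mat[:, ref_idx], trim_M, trim_A)
            for k in range(len(samples))
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        factors={s: float(f) for s, f in zip(samples, factors)},
        effective_library_size={
            s: float(f * n) for s, f, n in zip(samples, factors, lib)
        },
    )


# ---------------------------------------------------------------------------
# simulated-replicate DEG probability
# ---------------------------------------------------------------------------


def _dominance_fraction(
    sig_m: np.ndarray, sig_d: np.ndarray, noise_m: np.ndarray, noise_d: np.ndarray
) -> np.ndarray:
    """Fraction of noise points strictly dominated by each signal point.

    Strict inequality on both coordinates: ties count against the signal.
    Chunked broadcasting; fine for the tested scales (<= a few thousand
    genes, <= ~10^5 noise points).
    """
    n_noise = len(noise_m)
    out = np.empty(len(sig_m))
    chunk = max(1, int(2e7 / max(n_noise, 1)))
    for lo in range(0, len(sig_m), chunk):
        hi = lo + chunk
        dom = (sig_m[lo:hi, None] > noise_m[None, :]) & (
            sig_d[lo:hi, None] > noise_d[None, :]
        )
        out[lo:hi] = dom.mean(axis=1)
    return out


def noiseq_sim(
    counts: CountTable,
    norm: NormalizationResult,
    params: SimulationParams,
    k_zero: float = 0.5,
    q_threshold: float = 0.9,
    condition_order: tuple[str, str] | None = None,
) -> list[DEGRecord]:
    """Differential-expression probability from simulated technical replicates.

    Requires exactly one sample per condition (the no-replicate setting).
    For each condition, ``params.nss`` replicates are drawn as multinomial
    samples over genes (probabilities proportional to the normalized
    counts) with totals uniform on [(pnr - v) N, (pnr + v) N], N being the
    sample's library size. Replicates are scaled to counts-per-million and
    zeros replaced by ``k_zero``. The per-gene signal is M = log2 ratio
    and D = |difference| of the condition means; the noise distribution
    pools (|M|, D) over all within-condition replicate pairs and genes;
    q is the fraction of noise points strictly dominated by the signal.

    Deterministic given ``params.seed``; the random substream of each
    sample is keyed by its sorted identifier position, so relabeling the
    conditions flips M's sign without changing q.
    """
    conditions = list(dict.fromkeys(counts.conditions[s] for s in counts.samples))
    if len(conditions) != 2:
        raise ValueError("noiseq_sim requires exactly two conditions")
    if condition_order is not None:
        if set(condition_order) != set(conditions):
            raise ValueError(f"condition_order must be a permutation of {conditions}")
        conditions = list(condition_order)
    per_cond = {c: counts.samples_for(c) for c in conditions}
    for c, ss in per_cond.items():
        if len(ss) != 1:
            raise ValueError(
                f"condition {c!r} has {len(ss)} samples; noiseq_sim handles the "
                "no-replicate setting only — use a replicate-aware method instead"
            )
    sample_of = {c: per_cond[c][0] for c in conditions}

    genes = counts.genes
    mat = counts.counts.to_numpy(dtype=float)
    col_of = {s: i for i, s in enumerate(counts.samples)}

    # independent, label-stable random substreams: one per sample id
    children = np.random.SeedSequence(params.seed).spawn(len(counts.samples))
    rng_of = {s: np.random.default_rng(children[i]) for i, s in enumerate(sorted(counts.samples))}

    cpm = {}
    for c in conditions:
        s = sample_of[c]
        col = mat[:, col_of[s]]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} has zero total counts")
        probs = (col / norm.factors[s])
        probs = probs / probs.sum()
        rng = rng_of[s]
        lo = (params.pnr - params.v) * total
        hi = (params.pnr + params.v) * total
        reps = np.empty((params.nss, len(genes)))
        for r in range(params.nss):
            t = int(round(rng.uniform(lo, hi)))
            draw = rng.multinomial(t, probs).astype(float)
            x = draw / t * 1e6
            x[draw == 0] = k_zero
            reps[r] = x
        cpm[c] = reps

    c1, c2 = conditions
    mean1 = cpm[c1].mean(axis=0)
    mean2 = cpm[c2].mean(axis=0)
    # difference of logs (not log of ratio) so label swapping flips M exactly
    M = np.log2(mean1) - np.log2(mean2)
    D = np.abs(mean1 - mean2)

    noise_m_parts, noise_d_parts = [], []
    for c in conditions:
        reps = cpm[c]
        for i in range(params.nss):
            for j in range(i + 1, params.nss):
                noise_m_parts.append(np.abs(np.log2(reps[i]) - np.log2(reps[j])))
                noise_d_parts.append(np.abs(reps[i] - reps[j]))
    noise_m = np.concatenate(noise_m_parts)
    noise_d = np.concatenate(noise_d_parts)

    q = _dominance_fraction(np.abs(M), D, noise_m, noise_d)

    records = []
    for i, g in enumerate(genes):
        if q[i] >= q_threshold and M[i] > 0:
            direction = "up"
        elif q[i] >= q_threshold and M[i] < 0:
            direction = "down"
        else:
            direction = "none"
        records.append(
            DEGRecord(
                gene_id=g,
                mean_cond1=float(mean1[i]),
                mean_cond2=float(mean2[i]),
                M=float(M[i]),
                D=float(D[i]),
                q=float(q[i]),
                direction=direction,
            )
        )
    return records


def call_degs(
    records: Iterable[DEGRecord], q_threshold: float = 0.9
) -> tuple[set[str], set[str]]:
    """Partition genes into (up, down) sets at ``q >= q_threshold``."""
    up, down = set(), set()
    for r in records:
        if r.q >= q_threshold and r.M > 0:
            up.add(r.gene_id)
        elif r.q >= q_threshold and r.M < 0:
            down.add(r.gene_id)
    return up, down


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_DEG_COLUMNS = ["gene_id", "mean_cond1", "mean_cond2", "M", "D", "q", "direction"]


def write_deg_table(records: Iterable[DEGRecord], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_DEG_COLUMNS) + "\n")
        for r in records:
            out.write(
                f"{r.gene_id}\t{r.mean_cond1:.6g}\t{r.mean_cond2:.6g}\t"
                f"{r.M:.6g}\t{r.D:.6g}\t{r.q:.6g}\t{r.direction}\n"
            )


def read_deg_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "direction": str})
    return [
        DEGRecord(
            gene_id=row.gene_id,
            mean_cond1=float(row.mean_cond1),
            mean_cond2=float(row.mean_cond2),
            M=float(row.M),
            D=float(row.D),
            q=float(row.q),
            direction=row.direction,
        )
        for row in df.itertuples()
    ]
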