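"""Synthetic fixtures with known ground truth.

Promoter sets with planted TF binding sites encoding a known regulatory
network (hub "global" regulators plus sparse minor TFs), and
two-condition count tables with planted differentially expressed genes,
so every pipeline stage can be tested without external downloads.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats_io
from .formats_io import CountTable, SequenceSet
from .pfm_scan import BASES, PFM, reverse_complement


@dataclasses.dataclass
class FixtureTruth:
    """Ground truth recorded while generating a fixture."""

    true_edges: set[tuple[str, str]] = dataclasses.field(default_factory=set)
    planted_sites: list[tuple[str, str, int, str]] = dataclasses.field(default_factory=list)
    true_degs: dict[str, str] = dataclasses.field(default_factory=dict)
    true_fold_changes: dict[str, float] = dataclasses.field(default_factory=dict)
    global_regulators: set[str] = dataclasses.field(default_factory=set)
    seed: int = 0


def _random_background(rng: np.random.Generator, length: int, order: int) -> str:
    """I.i.d. uniform letters by default; order-2 draws from a random
    Dirichlet transition table to exercise the Markov background path."""
    if order == 0:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    n_ctx = 4**order
    trans = rng.dirichlet(np.full(4, 5.0), size=n_ctx)
    out = list(rng.integers(0, 4, size=order))
    code = 0
    for b in out:
        code = code * 4 + int(b)
    for _ in range(length - order):
        b = int(rng.choice(4, p=trans[code]))
        out.append(b)
        code = (code * 4 + b) % n_ctx
    return "".join(BASES[i] for i in out)


def _make_pfm(rng: np.random.Generator, tf_id: str, width: int, sharpness: float) -> PFM:
    consensus = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), (1.0 - sharpness) / 3.0)
    probs[np.arange(width), consensus] = sharpness
    return PFM(tf_id=tf_id, motif_id=f"{tf_id}_M1", probs=probs)


def generate_regulatory_fixture(
    n_tfs: int,
    n_genes: int,
    promoter_length: int = 1000,
    motif_length: int = 10,
    motif_sharpness: float = 0.95,
    edge_density: float = 0.02,
    n_global_regulators: int = 0,
    global_target_fraction: float = 0.55,
    seed: int = 0,
    plant: str = "consensus",
    background_order: int = 0,
) -> tuple[SequenceSet, list[PFM], FixtureTruth]:
    """Promoters with planted motif sites encoding a known GRN.

    The first ``n_global_regulators`` TFs are hubs, each targeting a
    random ``global_target_fraction`` of the genes; remaining TFs target
    each gene independently with probability ``edge_density``. One site
    per true edge is planted at a uniform random, non-overlapping
    position and strand. ``plant`` = "consensus" inserts the motif's
    consensus word; "sample" draws the word from the PFM columns.
    """
    if motif_length > promoter_length:
        raise ValueError("motif longer than promoter")
    if not (0 <= n_global_regulators <= n_tfs):
        raise ValueError("n_global_regulators must be within [0, n_tfs]")
    if plant not in ("consensus", "sample"):
        raise ValueError("plant must be 'consensus' or 'sample'")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    truth = FixtureTruth(seed=seed, global_regulators=set(tf_ids[:n_global_regulators]))

    pfms = [_make_pfm(rng, tf, motif_length, motif_sharpness) for tf in tf_ids]
    pfm_of = {p.tf_id: p for p in pfms}

    edges: list[tuple[str, str]] = []
    for i, tf in enumerate(tf_ids):
        if i < n_global_regulators:
            k = int(round(global_target_fraction * n_genes))
            targets = rng.choice(gene_ids, size=k, replace=False)
        else:
            mask = rng.random(n_genes) < edge_density
            targets = np.array(gene_ids, dtype=object)[mask]
        for g in targets:
            edges.append((tf, str(g)))
    truth.true_edges = set(edges)

    promoters = {
        g: _random_background(rng, promoter_length, background_order) for g in gene_ids
    }
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    w = motif_length
    for tf, gene in edges:
        pfm = pfm_of[tf]
        if plant == "consensus":
            word = pfm.consensus
        else:
            word = "".join(
                BASES[int(rng.choice(4, p=pfm.probs[i]))] for i in range(w)
            )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = word if strand == "+" else reverse_complement(word)
        pos = None
        for _ in range(200):  # rejection-sample a non-overlapping slot
            cand = int(rng.integers(0, promoter_length - w + 1))
            if all(cand + w <= lo or cand >= hi for lo, hi in occupied[gene]):
                pos = cand
                break
        if pos is None:
            continue  # promoter saturated; edge stays in truth without a site
        occupied[gene].append((pos, pos + w))
        seq = promoters[gene]
        promoters[gene] = seq[:pos] + inserted + seq[pos + w :]
        truth.planted_sites.append((tf, gene, pos + 1, strand))
    return SequenceSet(promoters), pfms, truth


def generate_counts_fixture(
    n_genes: int,
    depth: int,
    deg_fraction: float,
    fold_change: float,
    dispersion: float,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    lognormal_sigma: float = 1.0,
    condition_names: tuple[str, str] = ("light", "dark"),
) -> tuple[CountTable, FixtureTruth]:
    """Two-condition count table (one sample each) with planted DEGs.

    Baseline expression is log-normal; a ``deg_fraction`` subset is
    multiplied/divided by ``fold_change`` in condition 1 (half up, half
    down); counts are negative binomial with the given dispersion
    (variance = m + dispersion * m^2), Poisson when dispersion = 0. Both
    samples target the same total ``depth``.
    """
    if not (0 <= deg_fraction < 1):
        raise ValueError("deg_fraction must be in [0, 1)")
    if fold_change <= 0 or depth <= 0 or dispersion < 0:
        raise ValueError("fold_change and depth must be positive, dispersion >= 0")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    n = len(gene_ids)
    base = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n)

    truth = FixtureTruth(seed=seed)
    fc = np.ones(n)
    if deg_fraction > 0 and fold_change != 1.0:
        n_deg = int(round(deg_fraction * n))
        chosen = rng.choice(n, size=n_deg, replace=False)
        half = n_deg // 2
        fc[chosen[:half]] = fold_change
        fc[chosen[half:]] = 1.0 / fold_change
        for idx in chosen[:half]:
            truth.true_degs[gene_ids[idx]] = "up"
        for idx in chosen[half:]:
            truth.true_degs[gene_ids[idx]] = "down"
    truth.true_fold_changes = {g: float(f) for g, f in zip(gene_ids, fc)}

    def draw(mean_vec: np.ndarray) -> np.ndarray:
        mean_vec = mean_vec / mean_vec.sum() * depth
        if dispersion == 0:
            return rng.poisson(mean_vec)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean_vec * dispersion)
        return rng.poisson(lam)

    cond1, cond2 = condition_names
    counts = pd.DataFrame(
        {cond1: draw(base * fc), cond2: draw(base)},
        index=pd.Index(gene_ids, name="gene_id"),
        dtype=np.int64,
    )
    table = CountTable(counts=counts, conditions={cond1: cond1, cond2: cond2})
    return table, truth


def write_fixture_bundle(
    out_dir,
    promoters: SequenceSet,
    pfms: list[PFM],
    counts: CountTable,
    truth: FixtureTruth,
) -> dict[str, str]:
    """Write a complete fixture bundle loadable by the pipeline CLI.

    Produces promoters.fasta, pfms/<motif>.txt, counts.tsv, truth tables
    and a ready-to-run config.yaml; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pfms").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    paths = {
        "promoters": str(out / "promoters.fasta"),
        "pfms": str(out / "pfms"),
        "counts": str(out / "counts.tsv"),
        "config": str(out / "config.yaml"),
    }
    formats_io.write_fasta(promoters, paths["promoters"])
    for pfm in pfms:
        formats_io.write_pfm(pfm, out / "pfms" / f"{pfm.motif_id}.txt")
    formats_io.write_counts_table(counts, paths["counts"])

    pd.DataFrame(sorted(truth.true_edges), columns=["tf_id", "gene_id"]).to_csv(
        out / "truth" / "edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        truth.planted_sites, columns=["tf_id", "gene_id", "position", "strand"]
    ).to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_degs.items()), columns=["gene_id", "direction"]
    ).to_csv(out / "truth" / "degs.tsv", sep="\t", index=False)

    config = {
        "promoters": paths["promoters"],
        "pfms": paths["pfms"],
        "counts": paths["counts"],
        "conditions": {s: c for s, c in counts.conditions.items()},
        "out_dir": str(out / "results"),
        "markov_order": 2,
        "pvalue_threshold": 1e-5,
        "min_reads": 5,
        "pnr": 0.2,
        "nss": 10,
        "v": 0.02,
        "q_threshold": 0.9,
        "coverage_threshold": 0.9,
        "seed": truth.seed,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
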