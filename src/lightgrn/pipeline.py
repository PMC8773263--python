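"""End-to-end orchestration: scan -> build -> deg -> extract -> rank.

A single declarative config drives every stage; every parameter, input
checksum and the seed are recorded in a run manifest so results are
reproducible by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import deg as deg_mod
from . import formats_io, netstats, pfm_scan, subnetwork
from .grn_build import build_grn, hits_to_interactions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; the message names the failing stage."""


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds (defaults are the published values)."""

    promoters: str
    pfms: str
    counts: str
    out_dir: str
    conditions: dict[str, str] = dataclasses.field(default_factory=dict)
    gene_lists: dict[str, str] = dataclasses.field(default_factory=dict)
    markov_order: int = 2
    pvalue_threshold: float = 1e-5
    min_reads: int = 5
    pnr: float = 0.2
    nss: int = 10
    v: float = 0.02
    q_threshold: float = 0.9
    coverage_threshold: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")
        if not (0 < self.pvalue_threshold <= 1):
            raise ValueError("pvalue_threshold must be in (0, 1]")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not (0 <= self.q_threshold <= 1):
            raise ValueError("q_threshold must be in [0, 1]")
        if not (0 <= self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in [0, 1]")
        # pnr/nss/v domain checks are delegated to SimulationParams
        deg_mod.SimulationParams(pnr=self.pnr, nss=self.nss, v=self.v, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing all tables plus a manifest to ``out_dir``.

    Returns a result bundle with the in-memory objects and a summary dict.
    Stage errors propagate as :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # scan
    def _scan():
        promoters = formats_io.read_fasta(config.promoters)
        pfms = formats_io.read_cisbp_pfms(config.pfms)
        hits = pfm_scan.scan_promoters(
            promoters,
            pfms,
            m=config.markov_order,
            p_threshold=config.pvalue_threshold,
        )
        formats_io.write_hits(hits, out / "hits.tsv")
        return hits

    hits = stage("scan", _scan)

    # build
    def _build():
        grn = build_grn(hits_to_interactions(hits))
        formats_io.write_network(grn, out / "grn.tsv", dialect="edge_tsv")
        formats_io.write_network(grn, out / "grn.sif", dialect="sif")
        return grn

    grn = stage("build", _build)

    # deg
    def _deg():
        conditions = config.conditions
        table = formats_io.read_counts_table(config.counts, conditions)
        table = deg_mod.filter_low_counts(table, min_reads=config.min_reads)
        norm = deg_mod.tmm_normalize(table)
        params = deg_mod.SimulationParams(
            pnr=config.pnr, nss=config.nss, v=config.v, seed=config.seed
        )
        records = deg_mod.noiseq_sim(
            table, norm, params, q_threshold=config.q_threshold
        )
        deg_mod.write_deg_table(records, out / "degs.tsv")
        return records

    records = stage("deg", _deg)

    # extract
    def _extract():
        directions = {
            r.gene_id: r.direction for r in records if r.direction != "none"
        }
        light = subnetwork.extract_light_grn(grn, directions)
        light = subnetwork.annotate_edge_signs(light)
        formats_io.write_network(light, out / "light_grn.tsv", dialect="edge_tsv")
        return light

    light = stage("extract", _extract)

    # rank
    def _rank():
        measures = netstats.compute_node_measures(light)
        netstats.write_measures_table(measures, light, out / "measures.tsv")
        ranking = netstats.greedy_coverage_ranking(light)
        with open(out / "ranking.tsv", "w") as fh:
            fh.write("rank\tnode_id\tnew_targets\tcumulative_unique\tcumulative_fraction\n")
            for i, step in enumerate(ranking, start=1):
                fh.write(
                    f"{i}\t{step.node_id}\t{step.new_targets}\t"
                    f"{step.cumulative_unique}\t{step.cumulative_fraction:.6f}\n"
                )
        key_tfs = (
            netstats.select_key_tfs(ranking, config.coverage_threshold)
            if ranking
            else []
        )
        formats_io.write_gene_list(key_tfs, out / "key_tfs.txt")
        return measures, ranking, key_tfs

    measures, ranking, key_tfs = stage("rank", _rank)

    # pathway sub-networks
    def _pathways():
        results = {}
        for name, path in config.gene_lists.items():
            genes = formats_io.read_gene_list(path)
            sub = subnetwork.extract_pathway_subnetwork(light, genes)
            formats_io.write_network(sub, out / f"subnetwork_{name}.tsv", dialect="edge_tsv")
            results[name] = sub
        return results

    pathways = stage("pathways", _pathways)

    up = sorted(r.gene_id for r in records if r.direction == "up")
    down = sorted(r.gene_id for r in records if r.direction == "down")
    summary = {
        "grn": grn.summary(),
        "n_degs": len(up) + len(down),
        "n_up": len(up),
        "n_down": len(down),
        "light_grn": light.summary(),
        "key_tfs": key_tfs,
    }

    inputs = {"promoters": config.promoters, "counts": config.counts}
    manifest = {
        "config": dataclasses.asdict(config),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "seed": config.seed,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    logger.info(
        "pipeline complete: %d nodes / %d edges genome GRN; %d DEGs (%d up / %d down); "
        "light GRN %d nodes / %d edges; key TFs: %s",
        summary["grn"]["n_nodes"],
        summary["grn"]["n_edges"],
        summary["n_degs"],
        summary["n_up"],
        summary["n_down"],
        summary["light_grn"]["n_nodes"],
        summary["light_grn"]["n_edges"],
        ",".join(key_tfs),
    )
    return {
        "hits": hits,
        "grn": grn,
        "deg_records": records,
        "light_grn": light,
        "measures": measures,
        "ranking": ranking,
        "key_tfs": key_tfs,
        "pathways": pathways,
        "summary": summary,
        "out_dir": str(out),
    }
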