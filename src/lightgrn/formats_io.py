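"""Readers and writers for every external format the pipeline touches.

FASTA sequence sets, CIS-BP-style PFM text tables, TSV count tables,
plain-text gene lists, binding-site hit tables, and network exports
(SIF / edge TSV), plus upstream-region extraction from an annotated
genome. All readers reject malformed input with a position-bearing
error instead of silently coercing.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .grn_build import GRN, Interaction
from .pfm_scan import PFM, BindingSiteHit, reverse_complement

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_BAD_CHAR = re.compile(r"[^ACGTN]")


@dataclasses.dataclass
class SequenceSet:
    """Ordered identifier -> nucleotide string map (upper-case A/C/G/T/N)."""

    records: dict[str, str] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def items(self):
        return self.records.items()


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene coordinates: 1-based, fully closed, stranded."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: need 1 <= start <= end")


@dataclasses.dataclass
class CountTable:
    """Gene x sample integer counts with one condition label per sample."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids, dtype int64
    conditions: dict[str, str]  # sample -> condition

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative values")
        for sample in self.counts.columns:
            if sample not in self.conditions:
                raise ValueError(f"sample {sample!r} has no condition label")
        self.counts = self.counts.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Errors on duplicate identifiers, empty sequences, and characters
    outside A/C/G/T/N (reported with 1-based position).
    """
    records: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            if name in records:
                raise ValueError(f"duplicate FASTA identifier {name!r} in {path}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for {name!r} in {path}")
            bad = _BAD_CHAR.search(seq)
            if bad:
                raise ValueError(
                    f"invalid character {bad.group()!r} at position {bad.start() + 1} "
                    f"of sequence {name!r} in {path}"
                )
            records[name] = seq
    return SequenceSet(records)


def write_fasta(sequences: SequenceSet | Mapping[str, str], path, width: int = 70) -> None:
    records = sequences.records if isinstance(sequences, SequenceSet) else sequences
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# upstream extraction
# ---------------------------------------------------------------------------


def extract_upstream(
    genome: SequenceSet,
    annotations: Iterable[GeneAnnotation],
    length: int = 1000,
) -> SequenceSet:
    """Extract the ``length`` bases immediately 5' of each gene.

    For a + strand gene the window is genome[start-length .. start-1]; for
    a - strand gene the reverse complement of genome[end+1 .. end+length].
    Windows are truncated at contig boundaries; genes whose window is
    empty are omitted with a warning.
    """
    if length < 1:
        raise ValueError("length must be a positive integer")
    out: dict[str, str] = {}
    for ann in annotations:
        if ann.contig not in genome:
            raise KeyError(f"{ann.gene_id}: contig {ann.contig!r} not in genome")
        contig = genome[ann.contig]
        if ann.end > len(contig):
            raise ValueError(
                f"{ann.gene_id}: end {ann.end} beyond contig length {len(contig)}"
            )
        if ann.gene_id in out:
            raise ValueError(f"duplicate gene id {ann.gene_id!r} in annotations")
        if ann.strand == "+":
            lo = max(1, ann.start - length)
            hi = ann.start - 1
            window = contig[lo - 1 : hi]
        else:
            lo = ann.end + 1
            hi = min(len(contig), ann.end + length)
            window = reverse_complement(contig[lo - 1 : hi]) if lo <= hi else ""
        if not window:
            logger.warning("gene %s: empty upstream window, omitted", ann.gene_id)
            continue
        out[ann.gene_id] = window
    return SequenceSet(out)


# ---------------------------------------------------------------------------
# CIS-BP PFM tables
# ---------------------------------------------------------------------------


def _parse_pfm_file(path: Path) -> PFM:
    tf_id = motif_id = path.stem
    rows: list[list[float]] = []
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            key = fields[0].lower()
            if key == "tf" and len(fields) > 1:
                tf_id = fields[1]
                continue
            if key == "motif" and len(fields) > 1:
                motif_id = fields[1]
                continue
            if key == "pos":
                continue  # header line "Pos A C G T"
            if len(fields) == 5:
                fields = fields[1:]  # leading position index
            if len(fields) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 probabilities")
            try:
                row = [float(x) for x in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-numeric PFM entry") from exc
            total = sum(row)
            if abs(total - 1.0) > 1e-3:
                raise ValueError(
                    f"{path}:{line_no}: row sums to {total:.6g}, outside 1 +/- 1e-3"
                )
            rows.append([x / total for x in row])
    if not rows:
        raise ValueError(f"{path}: PFM has no positions")
    return PFM(tf_id=tf_id, motif_id=motif_id, probs=np.array(rows))


def read_cisbp_pfms(path) -> list[PFM]:
    """Read CIS-BP-style PFM text tables from one file or a directory.

    Layout: optional ``TF <id>`` / ``Motif <id>`` metadata lines, an
    optional ``Pos A C G T`` header, then one probability row per motif
    position. Rows are renormalized to sum exactly to 1 when within 1e-3
    of 1, otherwise an error is raised. TF/motif ids default to the file
    name stem.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        return [_parse_pfm_file(p) for p in files]
    return [_parse_pfm_file(path)]


def write_pfm(pfm: PFM, path) -> None:
    """Write one PFM in the CIS-BP text layout read by :func:`read_cisbp_pfms`."""
    with open(path, "w") as out:
        out.write(f"TF\t{pfm.tf_id}\n")
        out.write(f"Motif\t{pfm.motif_id}\n")
        out.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(pfm.probs, start=1):
            out.write(f"{i}\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# count tables and gene lists
# ---------------------------------------------------------------------------


def read_counts_table(path, condition_map: Mapping[str, str]) -> CountTable:
    """Read a TSV count table (gene ids in the first column).

    Every cell must be a non-negative integer; every sample column must
    appear in ``condition_map``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for sample in df.columns:
        if sample not in condition_map:
            raise ValueError(f"sample {sample!r} missing from condition map")
    parsed = {}
    for sample in df.columns:
        numeric = pd.to_numeric(df[sample], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer count at gene {gene!r}, sample {sample!r} in {path}"
            )
        if (numeric < 0).any():
            gene = df.index[(numeric < 0).to_numpy().nonzero()[0][0]]
            raise ValueError(f"negative count at gene {gene!r}, sample {sample!r}")
        parsed[sample] = numeric.astype(np.int64)
    counts = pd.DataFrame(parsed, index=df.index)
    return CountTable(counts=counts, conditions=dict(condition_map))


def write_counts_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line; blanks and '#' comments skipped."""
    out: list[str] = []
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token.split()[0])
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(f"{g}\n")


# ---------------------------------------------------------------------------
# binding-site hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "tf_id",
    "motif_id",
    "gene_id",
    "start",
    "strand",
    "matched_word",
    "score",
    "pvalue",
]


def write_hits(hits: Iterable[BindingSiteHit], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            out.write(
                f"{h.tf_id}\t{h.motif_id}\t{h.gene_id}\t{h.start}\t{h.strand}\t"
                f"{h.matched_word}\t{h.score:.6g}\t{h.pvalue:.6g}\n"
            )


def read_hits(path) -> list[BindingSiteHit]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing columns {missing}")
    return [
        BindingSiteHit(
            tf_id=row.tf_id,
            motif_id=row.motif_id,
            gene_id=row.gene_id,
            start=int(row.start),
            strand=row.strand,
            matched_word=row.matched_word,
            score=float(row.score),
            pvalue=float(row.pvalue),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def write_network(grn: GRN, path, dialect: str = "sif") -> None:
    """Write a network as SIF or edge TSV, edges in lexicographic order.

    SIF lines are ``regulator<TAB>regulates<TAB>target``. The edge TSV
    adds ``site_count`` and ``sign`` columns when any edge carries them.
    """
    if dialect not in ("sif", "edge_tsv"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    edges = sorted(grn.graph.edges(data=True))
    with open(path, "w") as out:
        if dialect == "sif":
            for u, v, _ in edges:
                out.write(f"{u}\tregulates\t{v}\n")
            return
        has_count = any("site_count" in d for _, _, d in edges)
        has_sign = any("sign" in d for _, _, d in edges)
        header = ["regulator", "target"]
        if has_count:
            header.append("site_count")
        if has_sign:
            header.append("sign")
        out.write("\t".join(header) + "\n")
        for u, v, d in edges:
            fields = [u, v]
            if has_count:
                fields.append(str(d.get("site_count", "")))
            if has_sign:
                fields.append(str(d.get("sign", "")))
            out.write("\t".join(fields) + "\n")


def read_network(path, dialect: str | None = None) -> GRN:
    """Read a network written by :func:`write_network` (dialect auto-detected)."""
    with open(path) as handle:
        first = handle.readline()
    if dialect is None:
        dialect = "edge_tsv" if first.startswith("regulator\t") else "sif"
    grn = GRN()
    if dialect == "sif":
        with open(path) as handle:
            for line_no, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}:{line_no}: malformed SIF line")
                u, _, v = fields
                grn.graph.add_edge(u, v)
        return grn
    df = pd.read_csv(path, sep="\t", dtype=str)
    for row in df.itertuples():
        attrs = {}
        if hasattr(row, "site_count") and not pd.isna(row.site_count):
            attrs["site_count"] = int(row.site_count)
        if hasattr(row, "sign") and isinstance(row.sign, str) and row.sign:
            attrs["sign"] = row.sign
        grn.graph.add_edge(row.regulator, row.target, **attrs)
    return grn
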