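"""Readers, writers, run configuration and domain record types.

All genomic coordinates at external interfaces are 1-based inclusive
(GFF3/BLAST convention).  Any half-open arithmetic is internal to the
modules that need it.  ``N`` bases count toward sequence length but never
toward GC numerators or match counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml
from Bio import SeqIO

__version__ = "0.1.0"

logger = logging.getLogger("evescreen")

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an external file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with linear/circular topology."""

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal symbols: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)


ANNOTATION_KINDS = frozenset({"gene", "transposable_element", "orf", "repeat", "eve"})


@dataclass
class AnnotationRecord:
    """One annotated interval on a scaffold (1-based inclusive)."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}-{self.end} on {self.scaffold_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")


class DepthTable(dict):
    """Mapping scaffold id -> mean sequencing depth (reads per base)."""

    def __setitem__(self, key: str, value: float) -> None:
        value = float(value)
        if value < 0:
            raise ValueError(f"negative depth for {key}: {value}")
        super().__setitem__(key, value)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "DepthTable":
        table = cls()
        for key, value in pairs:
            table[key] = value
        return table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_SCORE_WEIGHTS = {
    "premature_stop": 2,
    "depth_comparable": 1,
    "eukaryotic_gene_on_scaffold": 1,
    "te_on_scaffold": 1,
    "gc_similar": 1,
    "scaffold_exceeds_viral_size": 1,
}


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    The screening thresholds follow the published protocol: translated hits
    survive only with e-value strictly below ``max_evalue`` and query
    coverage strictly above ``min_query_coverage``; surviving hits within
    ``merge_gap_bp`` of each other are merged into one candidate locus.
    """

    max_evalue: float = 1e-5
    min_query_coverage: float = 0.20
    merge_gap_bp: int = 10
    merge_same_query_only: bool = False
    orf_min_length_nt: int = 150
    tandem_score_cutoff: int = 100
    ir_min_length_bp: int = 100
    ir_min_identity: float = 0.90
    depth_comparable_factor: float = 2.0
    gc_similarity_delta: float = 0.05
    long_scaffold_bp: int = 500_000
    score_weights: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_WEIGHTS))
    high_confidence_min_points: int = 5
    medium_confidence_min_points: int = 3
    search_seed_k: int = 4
    search_score_floor: float = 40.0
    search_xdrop: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_evalue):
            raise ValueError("max_evalue must be positive")
        if not (0 <= self.min_query_coverage < 1):
            raise ValueError("min_query_coverage must be in [0,1)")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be >= 0")
        if self.orf_min_length_nt < 6 or self.orf_min_length_nt % 3:
            raise ValueError("orf_min_length_nt must be >= 6 and divisible by 3")
        if self.depth_comparable_factor < 1:
            raise ValueError("depth_comparable_factor must be >= 1")
        if not (0 <= self.gc_similarity_delta <= 1):
            raise ValueError("gc_similarity_delta must be in [0,1]")
        if not (0 <= self.ir_min_identity <= 1):
            raise ValueError("ir_min_identity must be in [0,1]")
        if self.medium_confidence_min_points > self.high_confidence_min_points:
            raise ValueError("class thresholds out of order")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, lowercase is normalized to uppercase, and duplicate
    ids or empty records raise :class:`ParseError` naming the offender.
    """
    path = Path(path)
    _prevalidate_fasta(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), topology))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def _prevalidate_fasta(path: Path) -> None:
    """Line-level scan so parse errors can name a line number."""
    last_header_line = None
    has_seq = False
    n_headers = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if last_header_line is not None and not has_seq:
                    raise ParseError(
                        f"{path}:{last_header_line}: record has empty sequence"
                    )
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                last_header_line = lineno
                has_seq = False
                n_headers += 1
            else:
                if last_header_line is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                has_seq = True
    if n_headers == 0:
        raise ParseError(f"{path}: no FASTA records found")
    if not has_seq:
        raise ParseError(f"{path}:{last_header_line}: record has empty sequence")


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST-style 12-column tabular hits
# ---------------------------------------------------------------------------

def read_tabular_hits(path: str | Path):
    """Read 12-column BLAST tabular hits (outfmt-6 dialect).

    Columns: query, subject, pct identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore.  Subject
    coordinates are normalized so start <= end with the strand recorded.
    """
    from .homology import HomologyHit  # deferred: avoids circular import

    path = Path(path)
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, found {len(fields)}"
                )
            try:
                (query, subject, pident, alen, _mism, _gaps,
                 qs, qe, ss, se, evalue, bits) = fields
                qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
                pident, alen = float(pident), int(alen)
                evalue, bits = float(evalue), float(bits)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = "+" if ss <= se else "-"
            s_start, s_end = min(ss, se), max(ss, se)
            hits.append(
                HomologyHit(
                    query_id=query,
                    scaffold_id=subject,
                    q_start=qs,
                    q_end=qe,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    frame=None,
                    identity_fraction=pident / 100.0,
                    aln_length_aa=alen,
                    evalue=evalue,
                    bitscore=bits,
                )
            )
    logger.info("read_tabular_hits: %d hits from %s", len(hits), path)
    return hits


def write_tabular_hits(hits, path: str | Path) -> None:
    """Write hits in the 12-column dialect (round-trips with the reader)."""
    with open(path, "w") as handle:
        for h in hits:
            if h.strand == "-":
                ss, se = h.s_end, h.s_start
            else:
                ss, se = h.s_start, h.s_end
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.scaffold_id,
                        f"{h.identity_fraction * 100:.2f}",
                        str(h.aln_length_aa),
                        "0",
                        "0",
                        str(h.q_start),
                        str(h.q_end),
                        str(ss),
                        str(se),
                        f"{h.evalue:.3e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED annotations
# ---------------------------------------------------------------------------

_GFF_TYPE_TO_KIND = {
    "gene": "gene",
    "transposable_element": "transposable_element",
    "mobile_genetic_element": "transposable_element",
    "ORF": "orf",
    "orf": "orf",
    "CDS": "orf",
    "repeat_region": "repeat",
    "inverted_repeat": "repeat",
    "tandem_repeat": "repeat",
    "eve": "eve",
}

_KIND_TO_GFF_TYPE = {
    "gene": "gene",
    "transposable_element": "transposable_element",
    "orf": "ORF",
    "repeat": "repeat_region",
    "eve": "eve",
}


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read GFF3 feature lines into :class:`AnnotationRecord` objects.

    Feature types outside the pipeline's closed vocabulary are skipped with
    a log message; attributes are parsed as ``key=value`` pairs.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            kind = _GFF_TYPE_TO_KIND.get(ftype)
            if kind is None:
                logger.debug("read_gff3: skipping feature type %r", ftype)
                continue
            attributes = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item and "=" in item:
                    key, value = item.split("=", 1)
                    attributes[key] = value
            records.append(
                AnnotationRecord(seqid, int(start), int(end),
                                 strand if strand in "+-" else ".", kind, attributes)
            )
    logger.info("read_gff3: %d records from %s", len(records), path)
    return records


def write_gff3(records: Sequence[AnnotationRecord], path: str | Path,
               source: str = "evescreen") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for rec in records:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(rec.attributes.items()))
            handle.write(
                "\t".join(
                    [rec.scaffold_id, source, _KIND_TO_GFF_TYPE[rec.kind],
                     str(rec.start), str(rec.end), ".", rec.strand, ".",
                     attrs or "."]
                )
                + "\n"
            )


def read_bed(path: str | Path, kind: str = "transposable_element") -> list[AnnotationRecord]:
    """Read a BED file (0-based half-open) as annotations of the given kind."""
    path = Path(path)
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            records.append(
                AnnotationRecord(fields[0], int(fields[1]) + 1, int(fields[2]),
                                 strand, kind, {"Name": name} if name else {})
            )
    return records


def read_depth_table(path: str | Path) -> DepthTable:
    """Read a two-column TSV: scaffold id, mean depth."""
    path = Path(path)
    table = DepthTable()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected scaffold and depth")
            try:
                table[fields[0]] = float(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_depth_table(table: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        for key in sorted(table):
            handle.write(f"{key}\t{table[key]:.4f}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path, require_branch_lengths: bool = False) -> dendropy.Tree:
    """Read a single Newick tree; leaf labels must be unique.

    With ``require_branch_lengths`` a missing edge length raises a
    ``branch lengths required`` error, since patristic distances are
    undefined without them.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ParseError(f"duplicate leaf labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {dupes}")
    if require_branch_lengths:
        check_branch_lengths(tree)
    return tree


def check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("branch lengths required for patristic distances")
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(results: Sequence[Mapping], path: str | Path, format: str = "tsv",
                 config: RunConfig | None = None) -> None:
    """Write stage results with a config snapshot and the tool version.

    Column order is deterministic (first-seen key order across rows) and
    floats use a fixed ``%.6g`` precision, so identical results produce
    byte-identical files.
    """
    path = Path(path)
    columns: list[str] = []
    for row in results:
        for key in row:
            if key not in columns:
                columns.append(key)
    meta = {"version": __version__,
            "config": config.to_dict() if config is not None else None}
    if format == "tsv":
        with open(path, "w") as handle:
            handle.write(f"#evescreen_version={__version__}\n")
            if config is not None:
                handle.write("#config=" + json.dumps(meta["config"], sort_keys=True) + "\n")
            handle.write("\t".join(columns) + "\n")
            for row in results:
                handle.write(
                    "\t".join(_format_value(row.get(c, "")) for c in columns) + "\n"
                )
    elif format == "json":
        payload = {
            **meta,
            "results": [
                {c: row[c] for c in columns if c in row} for row in results
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=False,
                                   default=_format_value) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
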