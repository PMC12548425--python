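"""Translated homology search of viral proteins against host scaffolds.

The front end of the EVE screen: six-frame translation, a seeded
local-alignment search (exact k-mer seeds, ungapped X-drop extension,
gapped rescoring with BLOSUM62 and affine gaps), the strict e-value /
query-coverage filter, and the merge of adjacent surviving hits into
candidate loci.  The built-in search exists so the pipeline runs with no
external binary; externally produced 12-column tabular hits can be
substituted at any point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .io import SequenceRecord, reverse_complement

logger = logging.getLogger("evescreen")

# Karlin-Altschul constants for ungapped BLOSUM62 statistics
BLOSUM62_LAMBDA = 0.3176
BLOSUM62_K = 0.134

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class HomologyHit:
    """One translated-alignment hit of a viral protein on a scaffold.

    Query coordinates are 1-based amino acids; subject coordinates are
    1-based nucleotides with ``s_start <= s_end`` and the strand recorded.
    ``frame`` is +1..+3 / -1..-3 for hits from the built-in search and
    ``None`` for hits read from external tabular files.
    """

    query_id: str
    scaffold_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: Optional[int]
    identity_fraction: float
    aln_length_aa: int
    evalue: float
    bitscore: float
    raw_score: float = 0.0

    def __post_init__(self) -> None:
        if self.s_start > self.s_end:
            raise ValueError("subject coordinates must satisfy s_start <= s_end")
        if self.q_start > self.q_end:
            raise ValueError("query coordinates must satisfy q_start <= q_end")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    def coverage(self, query_length: int) -> float:
        return (self.q_end - self.q_start + 1) / query_length


@dataclass
class EveLocus:
    """A merged genomic interval with its supporting hits."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    member_hits: list = field(default_factory=list)

    @property
    def best_query(self) -> str:
        best = min(self.member_hits,
                   key=lambda h: (h.evalue, -h.bitscore, h.query_id))
        return best.query_id

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.member_hits)


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

def _build_codon_table() -> np.ndarray:
    table = CodonTable.unambiguous_dna_by_id[1]
    out = np.full(64, ord("X"), dtype=np.uint8)
    order = "ACGT"
    for i0, b0 in enumerate(order):
        for i1, b1 in enumerate(order):
            for i2, b2 in enumerate(order):
                codon = b0 + b1 + b2
                idx = 16 * i0 + 4 * i1 + i2
                if codon in table.stop_codons:
                    out[idx] = ord("*")
                else:
                    out[idx] = ord(table.forward_table[codon])
    return out


_CODON_AA = _build_codon_table()
_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def translate_frame(seq: str, offset: int = 0) -> str:
    """Translate one forward frame; trailing partial codons are dropped,
    stops render ``*`` and codons containing N render ``X``."""
    sub = seq[offset:]
    n = len(sub) - len(sub) % 3
    if n == 0:
        return ""
    codes = _BASE_CODE[np.frombuffer(sub[:n].encode(), dtype=np.uint8)]
    codes = codes.reshape(-1, 3)
    valid = (codes < 4).all(axis=1)
    idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
    idx[~valid] = 0
    aas = _CODON_AA[idx]
    aas[~valid] = ord("X")
    return aas.tobytes().decode()


def six_frame_translate(seq) -> dict[int, str]:
    """All six frame translations, keyed +1,+2,+3,-1,-2,-3.

    Frames +1..+3 read the forward strand at offsets 0..2; -1..-3 read
    the reverse complement at offsets 0..2.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else str(seq).upper()
    rc = reverse_complement(s)
    return {
        +1: translate_frame(s, 0),
        +2: translate_frame(s, 1),
        +3: translate_frame(s, 2),
        -1: translate_frame(rc, 0),
        -2: translate_frame(rc, 1),
        -3: translate_frame(rc, 2),
    }


def frame_to_genome(frame: int, aa_start: int, aa_end: int, L: int) -> tuple[int, int, str]:
    """Map 1-based aa positions in a frame translation to forward 1-based
    nt coordinates (s_start <= s_end) and a strand."""
    offset = abs(frame)  # 1..3
    nt_first = offset + 3 * (aa_start - 1)
    nt_last = offset + 3 * aa_end - 1
    if frame > 0:
        return nt_first, nt_last, "+"
    return L + 1 - nt_last, L + 1 - nt_first, "-"


# ---------------------------------------------------------------------------
# Seeded translated search
# ---------------------------------------------------------------------------

def _search_matrix():
    """BLOSUM62 with the X (unknown, e.g. translated N-gap) row hardened
    to -4: assembly-gap codons must terminate alignments, not be crossed
    at the near-zero cost the stock matrix assigns X against A/S/T."""
    matrix = substitution_matrices.load("BLOSUM62")
    xi = matrix.alphabet.index("X")
    for j in range(len(matrix.alphabet)):
        matrix[xi, j] = -4.0
        matrix[j, xi] = -4.0
    return matrix


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _search_matrix()
    # BLAST-style affine cost 11 + 1 per residue
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_BLOSUM = _search_matrix()
_B62_ALPHA = _BLOSUM.alphabet
_B62_INDEX = {c: i for i, c in enumerate(_B62_ALPHA)}
_B62 = np.array(_BLOSUM)


def _pair_score(a: str, b: str) -> float:
    ia = _B62_INDEX.get(a)
    ib = _B62_INDEX.get(b)
    if ia is None or ib is None:
        return -4.0
    return _B62[ia, ib]


def validate_protein(pid: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _AA_ALPHABET - {"X"}
    if bad:
        raise ValueError(f"query {pid!r} contains illegal amino acids: {sorted(bad)}")
    return seq


def search_translated(
    query_proteins: Mapping[str, str] | Sequence,
    scaffolds: Sequence[SequenceRecord],
    seed_k: int = 4,
    score_floor: float = 40.0,
    xdrop: float = 16.0,
    ungapped_floor: float = 25.0,
) -> list[HomologyHit]:
    """Seeded local alignment of proteins against all six scaffold frames.

    Exact ``seed_k``-mer seeds are extended ungapped with X-drop
    termination; surviving HSPs are rescored by local affine-gap
    alignment (BLOSUM62, open 11 / extend 1) in a window around the HSP.
    Hits with raw score >= ``score_floor`` are reported with approximate
    e-values E = K*m*n*exp(-lambda*S) using published ungapped BLOSUM62
    constants.  Output is deterministic and sorted by e-value.
    """
    if not query_proteins or not scaffolds:
        raise ValueError("need at least one query and one scaffold")
    if isinstance(query_proteins, Mapping):
        queries = {k: validate_protein(k, v) for k, v in query_proteins.items()}
    else:
        queries = {r.id: validate_protein(r.id, str(r.seq)) for r in query_proteins}

    # seed index over all query k-mers
    seed_index: dict[str, list[tuple[str, int]]] = {}
    for qid, qseq in queries.items():
        for i in range(len(qseq) - seed_k + 1):
            kmer = qseq[i : i + seed_k]
            if "X" in kmer:
                continue
            seed_index.setdefault(kmer, []).append((qid, i))

    aligner = _make_aligner()
    frames_total_aa = 0
    prelim: list[tuple] = []

    for scaffold in scaffolds:
        frames = six_frame_translate(scaffold)
        frames_total_aa += sum(len(p) for p in frames.values())
        for frame, subject in frames.items():
            hsps = _frame_hsps(queries, seed_index, subject, seed_k,
                               xdrop, ungapped_floor)
            for qid, q_lo, q_hi, s_lo, s_hi, _score in hsps:
                hit = _gapped_hit(aligner, queries[qid], qid, subject,
                                  s_lo, s_hi, scaffold, frame, score_floor)
                if hit is not None:
                    prelim.append(hit)

    hits = _dedupe_hits(prelim)
    # database-wide e-values: m = query length, n = total translated residues
    out = []
    for hit in hits:
        m = len(queries[hit.query_id])
        evalue = BLOSUM62_K * m * frames_total_aa * math.exp(
            -BLOSUM62_LAMBDA * hit.raw_score
        )
        bitscore = (BLOSUM62_LAMBDA * hit.raw_score - math.log(BLOSUM62_K)) / math.log(2)
        hit.evalue = evalue
        hit.bitscore = bitscore
        out.append(hit)
    out.sort(key=lambda h: (h.evalue, h.scaffold_id, h.s_start, h.query_id))
    logger.info("search_translated: %d queries x %d scaffolds -> %d hits",
                len(queries), len(scaffolds), len(out))
    return out


def _frame_hsps(queries, seed_index, subject: str, seed_k: int,
                xdrop: float, ungapped_floor: float):
    """Ungapped X-drop HSPs for one subject frame, deduped per diagonal."""
    hsps = []
    covered: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for j in range(len(subject) - seed_k + 1):
        kmer = subject[j : j + seed_k]
        entries = seed_index.get(kmer)
        if not entries:
            continue
        for qid, qi in entries:
            diag = j - qi
            spans = covered.get((qid, diag))
            if spans and any(lo <= j <= hi for lo, hi in spans):
                continue
            q_lo, q_hi, s_lo, s_hi, score = _ungapped_extend(
                queries[qid], subject, qi, j, seed_k, xdrop
            )
            covered.setdefault((qid, diag), []).append((s_lo, s_hi))
            if score >= ungapped_floor:
                hsps.append((qid, q_lo, q_hi, s_lo, s_hi, score))
    return hsps


def _ungapped_extend(query: str, subject: str, qi: int, sj: int, k: int,
                     xdrop: float):
    score = sum(_pair_score(query[qi + t], subject[sj + t]) for t in range(k))
    best = score
    q_hi, s_hi = qi + k - 1, sj + k - 1
    i, j = qi + k, sj + k
    while i < len(query) and j < len(subject):
        score += _pair_score(query[i], subject[j])
        if score > best:
            best, q_hi, s_hi = score, i, j
        if score < best - xdrop:
            break
        i += 1
        j += 1
    score = best
    q_lo, s_lo = qi, sj
    i, j = qi - 1, sj - 1
    while i >= 0 and j >= 0:
        score += _pair_score(query[i], subject[j])
        if score > best:
            best, q_lo, s_lo = score, i, j
        if score < best - xdrop:
            break
        i -= 1
        j -= 1
    return q_lo, q_hi, s_lo, s_hi, best


def _gapped_hit(aligner, qseq: str, qid: str, subject: str, s_lo: int, s_hi: int,
                scaffold: SequenceRecord, frame: int, score_floor: float):
    pad = 50
    w_lo = max(0, s_lo - pad)
    w_hi = min(len(subject), s_hi + 1 + pad)
    window = subject[w_lo:w_hi]
    if not window:
        return None
    alignments = aligner.align(qseq, window)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    score = float(aln.score)
    if score < score_floor:
        return None
    q_blocks, s_blocks = aln.aligned
    q_start0, q_end0 = int(q_blocks[0][0]), int(q_blocks[-1][1]) - 1
    s_start0, s_end0 = int(s_blocks[0][0]) + w_lo, int(s_blocks[-1][1]) - 1 + w_lo
    # identity over all alignment columns including gap columns
    matches = 0
    aligned_cols = 0
    prev_q_end = prev_s_end = None
    gap_cols = 0
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gap_cols += (qa - prev_q_end) + (sa - prev_s_end)
        for t in range(qb - qa):
            aligned_cols += 1
            if qseq[qa + t] == window[sa + t]:
                matches += 1
        prev_q_end, prev_s_end = qb, sb
    aln_length = aligned_cols + gap_cols
    nt_start, nt_end, strand = frame_to_genome(
        frame, s_start0 + 1, s_end0 + 1, len(scaffold.seq)
    )
    return HomologyHit(
        query_id=qid,
        scaffold_id=scaffold.id,
        q_start=q_start0 + 1,
        q_end=q_end0 + 1,
        s_start=nt_start,
        s_end=nt_end,
        strand=strand,
        frame=frame,
        identity_fraction=matches / aln_length if aln_length else 0.0,
        aln_length_aa=aln_length,
        evalue=0.0,
        bitscore=0.0,
        raw_score=score,
    )


def _dedupe_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Collapse overlapping hits of the same query/scaffold/frame to the
    best-scoring one."""
    hits = sorted(
        hits,
        key=lambda h: (-h.raw_score, h.scaffold_id, h.query_id,
                       h.s_start, h.s_end),
    )
    kept: list[HomologyHit] = []
    for hit in hits:
        redundant = False
        for other in kept:
            if (hit.query_id == other.query_id
                    and hit.scaffold_id == other.scaffold_id
                    and hit.frame == other.frame
                    and hit.s_start <= other.s_end
                    and other.s_start <= hit.s_end):
                redundant = True
                break
        if not redundant:
            kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Filtering and merging
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Sequence[HomologyHit],
    query_lengths: Mapping[str, int],
    max_evalue: float = 1e-5,
    min_query_coverage: float = 0.20,
) -> tuple[list[HomologyHit], dict]:
    """Keep hits with e-value strictly below ``max_evalue`` AND query
    coverage strictly above ``min_query_coverage``.

    Both tests are strict, matching the published protocol (e-value
    "smaller than" the cutoff; "more than" the coverage fraction).
    Input order is preserved; survivor counts are returned and logged.
    """
    survivors = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"hit references unknown query {hit.query_id!r}")
        if hit.evalue < max_evalue and hit.coverage(query_lengths[hit.query_id]) > min_query_coverage:
            survivors.append(hit)
    counts = {"input": len(hits), "retained": len(survivors),
              "removed": len(hits) - len(survivors)}
    logger.info(
        "filter_hits: %d -> %d (e-value < %g, coverage > %g)",
        counts["input"], counts["retained"], max_evalue, min_query_coverage,
    )
    return survivors, counts


def merge_adjacent_hits(
    hits: Iterable[HomologyHit],
    max_gap_bp: int = 10,
    same_query_only: bool = False,
) -> list[EveLocus]:
    """Merge hits on the same scaffold whose gap is within ``max_gap_bp``.

    Per scaffold (and per query when ``same_query_only``), hits sorted by
    subject start merge transitively whenever
    ``next.s_start - current_end <= max_gap_bp``; the locus span runs
    from the minimum start to the maximum end.  Merging is independent of
    input order, and output loci are pairwise separated by more than the
    gap, so re-merging is a no-op.
    """
    groups: dict[tuple, list[HomologyHit]] = {}
    for hit in hits:
        key = (hit.scaffold_id, hit.query_id) if same_query_only else (hit.scaffold_id,)
        groups.setdefault(key, []).append(hit)

    loci: list[EveLocus] = []
    for key in sorted(groups):
        members = sorted(groups[key],
                         key=lambda h: (h.s_start, h.s_end, h.query_id))
        cluster: list[HomologyHit] = []
        cur_end = None
        for hit in members:
            if cur_end is not None and hit.s_start - cur_end <= max_gap_bp:
                cluster.append(hit)
                cur_end = max(cur_end, hit.s_end)
            else:
                if cluster:
                    loci.append(_make_locus(cluster))
                cluster = [hit]
                cur_end = hit.s_end
        if cluster:
            loci.append(_make_locus(cluster))
    loci.sort(key=lambda l: (l.scaffold_id, l.start, l.end))
    logger.info("merge_adjacent_hits: %d loci (gap <= %d bp)", len(loci), max_gap_bp)
    return loci


def _make_locus(cluster: list[HomologyHit]) -> EveLocus:
    best = min(cluster, key=lambda h: (h.evalue, -h.bitscore, h.query_id))
    return EveLocus(
        scaffold_id=cluster[0].scaffold_id,
        start=min(h.s_start for h in cluster),
        end=max(h.s_end for h in cluster),
        strand=best.strand,
        member_hits=sorted(cluster, key=lambda h: (h.s_start, h.s_end, h.query_id)),
    )
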