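"""Selection and phylogeny/synteny analytics.

Pairwise dN/dS by the Nei-Gojobori (1986) counting method with
Jukes-Cantor correction — a closed-form stand-in for ML codon models
that supports the binary purifying-selection screen (omega < 1) —
plus patristic-distance summaries within/between virus families on
user-supplied trees, reciprocal-best-hit homolog pairing, and gene-order
synteny extraction for dot plots.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import check_branch_lengths

logger = logging.getLogger("evescreen")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignmentPair:
    """Two gap-aligned coding sequences of equal length (codon units)."""

    id_a: str
    id_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.codons_a) % 3:
            raise ValueError("alignment length must be divisible by 3")
        for name, seq in ((self.id_a, self.codons_a), (self.id_b, self.codons_b)):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"{name}: gaps must occur in whole-codon units "
                        f"(codon {i // 3 + 1}: {codon!r})"
                    )
                if codon in STOP_CODONS and i + 3 < len(seq):
                    raise ValueError(
                        f"{name}: internal stop codon at codon {i // 3 + 1}"
                    )

    def ungapped_columns(self):
        for i in range(0, len(self.codons_a), 3):
            ca, cb = self.codons_a[i : i + 3], self.codons_b[i : i + 3]
            if "-" not in ca and "-" not in cb and ca not in STOP_CODONS and cb not in STOP_CODONS:
                yield ca, cb


def back_translate_alignment(
    protein_alignment: Sequence[tuple[str, str]],
    cds_by_id: Mapping[str, str],
) -> list[tuple[str, str]]:
    """Expand a gapped protein alignment to codons using source CDSs.

    Each CDS must translate exactly to its degapped protein row (a
    trailing stop codon on the CDS is allowed and dropped); a mismatch
    raises an error naming the first offending position.  Amino-acid gaps
    expand to ``---``.
    """
    rows = []
    for pid, prot in protein_alignment:
        cds = cds_by_id.get(pid)
        if cds is None:
            raise KeyError(f"no CDS provided for {pid!r}")
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"{pid}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for i, codon in enumerate(codons, 1):
            if codon in STOP_CODONS:
                raise ValueError(f"{pid}: internal stop codon at position {i}")
        degapped = prot.replace("-", "").upper()
        if len(codons) != len(degapped):
            raise ValueError(
                f"{pid}: CDS has {len(codons)} codons but protein has "
                f"{len(degapped)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, degapped), 1):
            if codon in STOP_CODONS:
                raise ValueError(f"{pid}: internal stop codon at position {i}")
            if _AA.get(codon) != aa:
                raise ValueError(
                    f"{pid}: translation mismatch at position {i}: codon "
                    f"{codon} -> {_AA.get(codon)}, protein has {aa}"
                )
        out = []
        k = 0
        for aa in prot.upper():
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows.append((pid, "".join(out)))
    return rows


def codon_pair_from_proteins(protein_alignment, cds_by_id) -> CodonAlignmentPair:
    rows = back_translate_alignment(protein_alignment, cds_by_id)
    if len(rows) != 2:
        raise ValueError("expected exactly two aligned sequences")
    (ida, a), (idb, b) = rows
    return CodonAlignmentPair(ida, idb, a, b)


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

def _synonymous_sites(codon: str) -> float:
    """Fraction-weighted synonymous site count of a sense codon.

    Each position contributes (synonymous changes)/3; substitutions that
    create stop codons count as nonsynonymous, keeping S + N = 3 exactly.
    """
    s = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                s += 1 / 3
    return s


_SYN_SITES = {c: _synonymous_sites(c) for c in SENSE_CODONS}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _codon_path_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two
    sense codons over all shortest substitution paths.

    Paths passing through stop codons are excluded (falling back to all
    paths if every path is blocked); remaining paths weight equally.
    """
    if ca == cb:
        return 0.0, 0.0
    key = (ca, cb)
    cached = _PATH_CACHE.get(key)
    if cached is not None:
        return cached
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        # every route crosses a stop: average the per-step classification
        # over all orders, scoring stop-crossing steps as nonsynonymous
        paths = []
        for order in itertools.permutations(diff_pos):
            cur = ca
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS or _AA.get(cur, "*") != _AA.get(nxt, "*"):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    _PATH_CACHE[key] = (sd, nd)
    return sd, nd


@dataclass
class SelectionResult:
    """NG86 estimates for one aligned coding-sequence pair."""

    id_a: str
    id_b: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    purifying: Optional[bool]
    flags: list = field(default_factory=list)


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(pair: CodonAlignmentPair) -> SelectionResult:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

    Synonymous/nonsynonymous sites are counted per codon by averaging
    over the three positions and possible substitutions under the
    standard code (site totals averaged between the two sequences);
    differences are counted by equal-weight averaging over all shortest
    substitution paths, excluding paths through stop codons.  omega is
    defined only when dS > 0; pS or pN >= 3/4 leaves the corresponding
    rate undefined and flagged.
    """
    S1 = S2 = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in pair.ungapped_columns():
        n_codons += 1
        S1 += _SYN_SITES[ca]
        S2 += _SYN_SITES[cb]
        sd, nd = _codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no ungapped codon columns to compare")
    S = (S1 + S2) / 2
    N = 3 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    flags = []
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if dS is None:
        flags.append("dS_saturated")
    if dN is None:
        flags.append("dN_saturated")
    omega: Optional[float] = None
    if dS is not None and dN is not None:
        if dS > 0:
            omega = dN / dS
        else:
            flags.append("omega_undefined_dS_zero")
    purifying = (omega < 1) if omega is not None else None
    return SelectionResult(
        id_a=pair.id_a, id_b=pair.id_b, n_codons=n_codons,
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, purifying=purifying, flags=flags,
    )


def purifying_screen(results: Sequence[SelectionResult],
                     threshold: float = 1.0) -> dict:
    """Flag results with omega below ``threshold``; undefined omegas are
    excluded and counted separately."""
    flags = []
    n_purifying = n_not = n_undefined = 0
    for res in results:
        if res.omega is None:
            flags.append(None)
            n_undefined += 1
        elif res.omega < threshold:
            flags.append(True)
            n_purifying += 1
        else:
            flags.append(False)
            n_not += 1
    return {
        "flags": flags,
        "n_purifying": n_purifying,
        "n_not_purifying": n_not,
        "n_undefined": n_undefined,
        "threshold": threshold,
    }


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric leaf x leaf matrix of path-length distances.

    d(i,j) sums the branch lengths on the unique i-j path; the diagonal
    is zero.  Missing branch lengths raise an explicit error.
    """
    check_branch_lengths(tree)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(labels) < 2:
        raise ValueError("patristic matrix needs >= 2 leaves")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class FamilyDistanceSummary:
    """Patristic distance ranges within and between virus families."""

    within: dict
    between: dict
    pooled_within: Optional[dict]
    pooled_between: Optional[dict]


def _stats(values: list[float]) -> dict:
    return {
        "min": min(values),
        "max": max(values),
        "mean": sum(values) / len(values),
        "n_pairs": len(values),
    }


def family_distance_summary(
    matrix: pd.DataFrame, family_map: Mapping[str, str]
) -> FamilyDistanceSummary:
    """Summarize distances within each family and between family pairs."""
    missing = [l for l in matrix.index if l not in family_map]
    if missing:
        raise ValueError(f"leaves without family assignment: {missing}")
    within: dict[str, list[float]] = {}
    between: dict[tuple[str, str], list[float]] = {}
    labels = list(matrix.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = float(matrix.at[a, b])
            fa, fb = family_map[a], family_map[b]
            if fa == fb:
                within.setdefault(fa, []).append(d)
            else:
                between.setdefault(tuple(sorted((fa, fb))), []).append(d)
    families = set(family_map[l] for l in labels)
    for fam in families - set(within):
        logger.warning("family %r has a single member: no within-family pairs", fam)
    w_all = [d for vals in within.values() for d in vals]
    b_all = [d for vals in between.values() for d in vals]
    return FamilyDistanceSummary(
        within={f: _stats(v) for f, v in sorted(within.items())},
        between={p: _stats(v) for p, v in sorted(between.items())},
        pooled_within=_stats(w_all) if w_all else None,
        pooled_between=_stats(b_all) if b_all else None,
    )


# ---------------------------------------------------------------------------
# Reciprocal best hits and synteny
# ---------------------------------------------------------------------------

def _best_by_query(hits) -> dict[str, str]:
    """Best subject per query: highest bitscore, ties by lower e-value
    then lexicographically smaller subject id."""
    best: dict[str, tuple] = {}
    for h in hits:
        key = (-h.bitscore, h.evalue, h.scaffold_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(hits_a_vs_b, hits_b_vs_a) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit.

    Hits carry ``query_id``, ``scaffold_id`` (the subject), ``bitscore``
    and ``evalue``.  Output is sorted and symmetric under swapping the
    two input sets.
    """
    best_ab = _best_by_query(hits_a_vs_b)
    best_ba = _best_by_query(hits_b_vs_a)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


@dataclass
class SyntenyPair:
    """One homolog pair with its rank in each genome's gene order."""

    rank_a: int
    rank_b: int
    gene_a: str
    gene_b: str
    same_strand: bool


def synteny_orders(
    genes_a: Sequence[tuple[str, int, str]],
    genes_b: Sequence[tuple[str, int, str]],
    homolog_pairs: Sequence[tuple[str, str]],
) -> list[SyntenyPair]:
    """Gene-order ranks of homolog pairs for a synteny dot plot.

    ``genes_a``/``genes_b`` are (gene_id, start, strand) triples; rank is
    the 1-based index in start-coordinate order.  A gene appearing twice
    in the pair list is an error.
    """
    def ranks(genes):
        out = {}
        strands = {}
        for rank, (gid, _start, strand) in enumerate(
            sorted(genes, key=lambda g: (g[1], g[0])), 1
        ):
            if gid in out:
                raise ValueError(f"duplicate gene id {gid!r}")
            out[gid] = rank
            strands[gid] = strand
        return out, strands

    rank_a, strand_a = ranks(genes_a)
    rank_b, strand_b = ranks(genes_b)
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    out = []
    for ga, gb in homolog_pairs:
        if ga in seen_a or gb in seen_b:
            raise ValueError(f"gene appears twice in pair list: {ga!r}/{gb!r}")
        seen_a.add(ga)
        seen_b.add(gb)
        if ga not in rank_a:
            raise KeyError(f"unknown gene {ga!r} in genome A")
        if gb not in rank_b:
            raise KeyError(f"unknown gene {gb!r} in genome B")
        out.append(
            SyntenyPair(rank_a[ga], rank_b[gb], ga, gb,
                        strand_a[ga] == strand_b[gb])
        )
    out.sort(key=lambda p: p.rank_a)
    return out
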