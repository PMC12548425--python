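"""Evidence-based confidence scoring of candidate endogenous viral elements.

Each candidate locus is scored on six genomic features indicative of a
genuine germline integration rather than contamination or an exogenous
virus: premature stop codons in the viral homology span (2 points),
sequencing depth comparable to host scaffolds, annotated eukaryotic
(insect) genes on the scaffold, transposable elements on the scaffold,
host-like GC content, and a scaffold length exceeding known exogenous
viral genome sizes (>500 kb) — 1 point each.  Totals partition into
high (>4), medium (3-4) and low (<=2) confidence classes.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .features import gc_content
from .homology import EveLocus, translate_frame
from .io import (AnnotationRecord, DEFAULT_SCORE_WEIGHTS, DepthTable,
                 RunConfig, SequenceRecord, reverse_complement)

logger = logging.getLogger("evescreen")

EVIDENCE_FIELDS = (
    "premature_stop",
    "depth_comparable",
    "eukaryotic_gene_on_scaffold",
    "te_on_scaffold",
    "gc_similar",
    "scaffold_exceeds_viral_size",
)

_CLASS_RANK = {"low": 0, "medium": 1, "high": 2}


@dataclass
class EveEvidence:
    """The six boolean evidence features, each with its numeric support."""

    premature_stop: bool = False
    depth_comparable: bool = False
    eukaryotic_gene_on_scaffold: bool = False
    te_on_scaffold: bool = False
    gc_similar: bool = False
    scaffold_exceeds_viral_size: bool = False
    # numeric support
    stop_count: int = 0
    locus_depth: Optional[float] = None
    host_median_depth: Optional[float] = None
    scaffold_gc: Optional[float] = None
    host_gc_mean: Optional[float] = None
    host_gc_sd: Optional[float] = None
    scaffold_length: Optional[int] = None
    unavailable: list = field(default_factory=list)


@dataclass
class EveScore:
    """Total points and confidence class for one locus."""

    locus: Optional[EveLocus]
    points: int
    confidence: str
    evidence: Optional[EveEvidence] = None


# ---------------------------------------------------------------------------
# Premature stop detection
# ---------------------------------------------------------------------------

def detect_premature_stops(
    locus: EveLocus, scaffolds: Mapping[str, SequenceRecord]
) -> tuple[int, list[int]]:
    """Count internal stop codons within each member hit's span.

    Each member's scaffold span is translated in its own frame/strand; a
    stop at the terminal codon of a span is not premature and is
    excluded.  Returns the locus-level sum and the per-member counts.
    """
    scaffold = scaffolds.get(locus.scaffold_id)
    if scaffold is None:
        raise KeyError(f"scaffold {locus.scaffold_id!r} not provided")
    counts = []
    for hit in locus.member_hits:
        if hit.s_end > len(scaffold.seq) or hit.s_start < 1:
            raise ValueError(
                f"hit span {hit.s_start}-{hit.s_end} outside scaffold "
                f"{locus.scaffold_id} (length {len(scaffold.seq)})"
            )
        span = scaffold.seq[hit.s_start - 1 : hit.s_end]
        if hit.strand == "-":
            span = reverse_complement(span)
        peptide = translate_frame(span, 0)
        internal = peptide[:-1] if peptide else ""
        counts.append(internal.count("*"))
    return sum(counts), counts


# ---------------------------------------------------------------------------
# Host background and evidence extraction
# ---------------------------------------------------------------------------

def is_insect_gene(ann: AnnotationRecord) -> bool:
    if ann.kind != "gene":
        return False
    value = str(ann.attributes.get("taxon", ann.attributes.get("insect", ""))).lower()
    return value in ("insect", "insecta", "true", "1", "yes")


def host_background(
    scaffolds: Mapping[str, SequenceRecord],
    annotations: Sequence[AnnotationRecord],
    depth_table: Mapping[str, float],
    loci: Sequence[EveLocus] = (),
) -> dict:
    """Background depth/GC statistics from host scaffolds.

    Host scaffolds are those carrying at least one insect-assigned gene
    and no candidate locus — a proxy for curated single-copy host
    scaffolds when no ortholog assessment is available.
    """
    with_gene = {a.scaffold_id for a in annotations if is_insect_gene(a)}
    with_locus = {l.scaffold_id for l in loci}
    host_ids = sorted((with_gene - with_locus) & set(scaffolds))
    if not host_ids:
        raise ValueError("no host background scaffolds (insect gene, no locus)")
    depths = [depth_table[s] for s in host_ids if s in depth_table]
    gcs = [gc_content(scaffolds[s]) for s in host_ids]
    return {
        "scaffold_ids": host_ids,
        "median_depth": statistics.median(depths) if depths else None,
        "gc_mean": statistics.fmean(gcs),
        "gc_sd": statistics.stdev(gcs) if len(gcs) > 1 else 0.0,
    }


def extract_evidence(
    locus: EveLocus,
    scaffolds: Mapping[str, SequenceRecord],
    annotations: Sequence[AnnotationRecord],
    depth_table: Mapping[str, float],
    host_stats: Mapping,
    config: RunConfig | None = None,
    stop_count: int | None = None,
) -> EveEvidence:
    """Evaluate the six evidence features for one locus.

    Scaffold-level features (depth, genes, TEs, GC, length) are shared by
    all loci on a scaffold; the premature-stop count is per locus.
    Unavailable evidence (e.g. a missing depth entry) marks the feature
    false and records it in ``unavailable`` rather than imputing.
    """
    config = config or RunConfig()
    scaffold = scaffolds.get(locus.scaffold_id)
    if scaffold is None:
        raise KeyError(f"scaffold {locus.scaffold_id!r} not provided")
    if stop_count is None:
        stop_count, _ = detect_premature_stops(locus, scaffolds)

    evidence = EveEvidence(stop_count=stop_count,
                           premature_stop=stop_count >= 1)

    sid = locus.scaffold_id
    depth = depth_table.get(sid)
    median = host_stats.get("median_depth")
    if depth is None or median is None:
        evidence.unavailable.append("depth_comparable")
        logger.warning("no depth entry for %s; depth criterion scores 0", sid)
    else:
        factor = config.depth_comparable_factor
        evidence.locus_depth = depth
        evidence.host_median_depth = median
        evidence.depth_comparable = median / factor <= depth <= median * factor

    scaffold_anns = [a for a in annotations if a.scaffold_id == sid]
    evidence.eukaryotic_gene_on_scaffold = any(
        is_insect_gene(a) for a in scaffold_anns
    )
    evidence.te_on_scaffold = any(
        a.kind == "transposable_element" for a in scaffold_anns
    )

    evidence.scaffold_gc = gc_content(scaffold)
    evidence.host_gc_mean = host_stats.get("gc_mean")
    evidence.host_gc_sd = host_stats.get("gc_sd")
    if evidence.host_gc_mean is None:
        evidence.unavailable.append("gc_similar")
    else:
        evidence.gc_similar = (
            abs(evidence.scaffold_gc - evidence.host_gc_mean)
            <= config.gc_similarity_delta
        )

    evidence.scaffold_length = len(scaffold.seq)
    evidence.scaffold_exceeds_viral_size = (
        evidence.scaffold_length > config.long_scaffold_bp
    )
    return evidence


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

def score_eve(
    evidence: EveEvidence,
    weights: Mapping[str, int] | None = None,
    locus: EveLocus | None = None,
    high_min: int = 5,
    medium_min: int = 3,
) -> EveScore:
    """Weighted sum of the evidence booleans and its confidence class.

    Default weights: premature stops 2 points, every other feature 1.
    """
    weights = dict(DEFAULT_SCORE_WEIGHTS if weights is None else weights)
    points = sum(
        weights[name] for name in EVIDENCE_FIELDS if getattr(evidence, name)
    )
    return EveScore(
        locus=locus,
        points=points,
        confidence=classify_points(points, high_min=high_min, medium_min=medium_min),
        evidence=evidence,
    )


def classify_points(points: int, high_min: int = 5, medium_min: int = 3) -> str:
    """Map a total score to its confidence class.

    With the defaults: high for >4 points, medium for 3-4, low for <=2 —
    the classes partition 0..7 as {0,1,2}, {3,4}, {5,6,7}.
    """
    if points >= high_min:
        return "high"
    if points >= medium_min:
        return "medium"
    return "low"


def census(
    scores: Sequence[EveScore],
    threshold_class: str = "high",
    species_of_scaffold: Mapping[str, str] | None = None,
) -> dict:
    """Cohort-level summary of scored loci.

    Reports the candidate count, counts per confidence class and per
    scaffold, and a species x viral-gene boolean presence matrix: a gene
    is present for a species when at least one of its loci with that
    best-supporting query reaches ``threshold_class`` (or better).
    """
    if threshold_class not in _CLASS_RANK:
        raise ValueError(f"unknown class {threshold_class!r}")
    per_class = {"high": 0, "medium": 0, "low": 0}
    per_scaffold: dict[str, int] = {}
    presence: dict[str, set] = {}
    min_rank = _CLASS_RANK[threshold_class]
    for score in scores:
        per_class[score.confidence] += 1
        if score.locus is not None:
            sid = score.locus.scaffold_id
            per_scaffold[sid] = per_scaffold.get(sid, 0) + 1
            if _CLASS_RANK[score.confidence] >= min_rank:
                species = (
                    species_of_scaffold.get(sid, sid)
                    if species_of_scaffold else sid
                )
                presence.setdefault(species, set()).add(score.locus.best_query)

    genes = sorted({g for s in presence.values() for g in s})
    matrix = {
        species: {g: g in present for g in genes}
        for species, present in sorted(presence.items())
    }
    result = {
        "n_candidates": len(scores),
        "per_class": per_class,
        "n_meeting_threshold": sum(
            1 for s in scores if _CLASS_RANK[s.confidence] >= min_rank
        ),
        "threshold_class": threshold_class,
        "per_scaffold": dict(sorted(per_scaffold.items())),
        "presence_matrix": matrix,
    }
    logger.info(
        "census: %d candidates (high=%d, medium=%d, low=%d)",
        result["n_candidates"], per_class["high"], per_class["medium"],
        per_class["low"],
    )
    return result
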