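"""End-to-end screening pipeline: scan -> filter -> merge -> score.

A thin orchestration layer over the stage modules; every stage logs its
input and survivor counts with the thresholds actually applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .homology import (HomologyHit, filter_hits, merge_adjacent_hits,
                       search_translated)
from .io import AnnotationRecord, RunConfig, SequenceRecord
from .scoring import (EveScore, census, detect_premature_stops,
                      extract_evidence, host_background, score_eve)

logger = logging.getLogger("evescreen")


@dataclass
class ScreenResult:
    """Loci, per-locus scores and the cohort census of one run."""

    hits: list
    retained_hits: list
    loci: list
    scores: list
    census: dict
    host_stats: dict
    counts: dict = field(default_factory=dict)


def run_screen(
    scaffolds: Sequence[SequenceRecord],
    query_proteins: Mapping[str, str],
    annotations: Sequence[AnnotationRecord],
    depth_table: Mapping[str, float],
    config: RunConfig | None = None,
    hits: Sequence[HomologyHit] | None = None,
    species_of_scaffold: Mapping[str, str] | None = None,
    census_threshold: str = "high",
) -> ScreenResult:
    """Run the full EVE screen on one set of scaffolds.

    With ``hits`` given (e.g. from an external translated search in
    tabular form), the built-in search is bypassed.
    """
    config = config or RunConfig()
    if hits is None:
        hits = search_translated(
            query_proteins, scaffolds,
            seed_k=config.search_seed_k,
            score_floor=config.search_score_floor,
            xdrop=config.search_xdrop,
        )
    query_lengths = {k: len(v) for k, v in query_proteins.items()}
    retained, filter_counts = filter_hits(
        hits, query_lengths,
        max_evalue=config.max_evalue,
        min_query_coverage=config.min_query_coverage,
    )
    loci = merge_adjacent_hits(retained, max_gap_bp=config.merge_gap_bp,
                               same_query_only=config.merge_same_query_only)
    scaffold_map = {s.id: s for s in scaffolds}
    host_stats = host_background(scaffold_map, annotations, depth_table, loci)
    scores: list[EveScore] = []
    for locus in loci:
        stop_count, _ = detect_premature_stops(locus, scaffold_map)
        evidence = extract_evidence(
            locus, scaffold_map, annotations, depth_table, host_stats,
            config=config, stop_count=stop_count,
        )
        scores.append(
            score_eve(evidence, config.score_weights, locus=locus,
                      high_min=config.high_confidence_min_points,
                      medium_min=config.medium_confidence_min_points)
        )
    result_census = census(scores, threshold_class=census_threshold,
                           species_of_scaffold=species_of_scaffold)
    counts = {
        "n_hits": len(hits),
        "n_retained_hits": len(retained),
        "n_loci": len(loci),
        **{f"filter_{k}": v for k, v in filter_counts.items()},
    }
    logger.info("run_screen: %(n_hits)d hits -> %(n_retained_hits)d retained "
                "-> %(n_loci)d loci", counts)
    return ScreenResult(
        hits=list(hits), retained_hits=retained, loci=loci, scores=scores,
        census=result_census, host_stats=host_stats, counts=counts,
    )
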