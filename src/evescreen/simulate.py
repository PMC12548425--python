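"""Ground-truthed synthetic data for every pipeline stage.

Generates host scaffolds of controlled GC and length, annotated circular
viral genomes whose ORF/repeat truth is exactly recoverable, implanted
and degraded viral fragments realizing chosen evidence profiles (with
the expected locus count, score and confidence class recorded), and
codon sequences evolved under a specified dN/dS.

Exact ORF recovery is guaranteed by construction, not by rejection
sampling: a fixed 15-nt codon-aligned "stop cassette" carrying stop
codons in both shifted forward frames and all three reverse frames (and
free of ATG/CAT) is salted through ORF interiors and spacers, and
spacers additionally carry frequent in-frame stop codons, so no reading
frame outside the implanted ORFs stays open long enough to reach the
minimum ORF length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .features import STOP_CODONS
from .homology import translate_frame
from .io import (AnnotationRecord, DepthTable, RunConfig, SequenceRecord)
from .scoring import DEFAULT_SCORE_WEIGHTS, classify_points

logger = logging.getLogger("evescreen")

# Stop cassettes: 15-nt codon-aligned motifs with stop codons in both
# shifted forward frames and all three reverse frames, no ATG/CAT even
# when abutted against themselves, and sense codons in frame.  Their
# amino-acid translations share no 4-mer, so cassettes salted into
# different synthetic genes never seed spurious cross-gene alignments.
CASSETTES = (
    "GTTAACTACTTAGCA",  # VNYLA
    "CTAACTAAAATTCAG",  # LTKIQ
    "GTCCTAATTAACTAC",  # VLINY
    "CCTAGTCAATTAGCC",  # PSQLA
    "TTAACTAGTCAGAAG",  # LTSQK
    "CTAGTTCAGCCTAAT",  # LVQPN
    "TCTAGCTTAACTCAG",  # SSLTQ
    "CTAGACCTTAGTTAT",  # LDLSY
    "CTTAGTCAATTAAGG",  # LSQLR
    "CTGCTAGTTAGTTAC",  # LLVSY
    "TTAACTAGGTGTCAG",  # LTRCQ
    "CTAGTTACCTATAAC",  # LVTYN
    "TTAGCTAACTACCCT",  # LANYP
)
CASSETTE = CASSETTES[0]

_BASES = "ACGT"
_SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in _BASES for b in _BASES for c in _BASES
        if a + b + c not in STOP_CODONS
    )
)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_bases(rng, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _codon_weights(gc: float, codons: Sequence[str]) -> np.ndarray:
    pb = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
    return w / w.sum()


def _random_sense_codons(rng, n: int, gc: float) -> list[str]:
    w = _codon_weights(gc, _SENSE_CODONS)
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=w)
    return [_SENSE_CODONS[i] for i in idx]


def _random_codons_any(rng, n: int, gc: float) -> list[str]:
    all_codons = tuple(
        sorted(a + b + c for a in _BASES for b in _BASES for c in _BASES)
    )
    w = _codon_weights(gc, all_codons)
    idx = rng.choice(len(all_codons), size=n, p=w)
    return [all_codons[i] for i in idx]


# ---------------------------------------------------------------------------
# Host scaffolds
# ---------------------------------------------------------------------------

def generate_host_scaffold(length: int, gc: float, seed,
                           scaffold_id: str = "scaffold_1") -> SequenceRecord:
    """I.i.d. host scaffold: P(G)+P(C) = gc, split evenly; deterministic
    per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0,1]")
    return SequenceRecord(scaffold_id, _random_bases(_rng(seed), length, gc))


# ---------------------------------------------------------------------------
# Annotated viral genome
# ---------------------------------------------------------------------------

def _spacer(rng, n_periods: int, gc: float) -> str:
    """Inter-feature spacer: per period, 8 unconstrained codons, an
    in-frame TAA, and the stop cassette.  Ends with the cassette, whose
    codons contain no ATG, so no open frame survives into the next
    feature."""
    parts = []
    for _ in range(max(1, n_periods)):
        parts.extend(_random_codons_any(rng, 8, gc))
        parts.append("TAA")
        parts.append(CASSETTE)
    return "".join(parts)


def _orf_sequence(rng, n_codons: int, gc: float,
                  cassette: str = CASSETTE) -> str:
    """ATG + interior sense codons (cassette every <=14 codons) + TAA."""
    if n_codons < 12:
        raise ValueError("ORF needs >= 12 codons")
    interior = []
    remaining = n_codons - 2
    while remaining > 0:
        chunk = min(14, remaining)
        interior.extend(_random_sense_codons(rng, chunk, gc))
        remaining -= chunk
        if remaining >= 5:
            interior.append(cassette)
            remaining -= 5
    return "ATG" + "".join(interior) + "TAA"


def _safe_segment(rng, length: int, gc: float, forbid_start=("TG",),
                  forbid_end=("CA",)) -> str:
    """Random segment free of ATG/CAT anywhere (so no reading frame can
    open inside it), with constrained first/last dinucleotides so motifs
    cannot form across its junctions either."""
    seq = list(_random_bases(rng, length, gc))
    for _ in range(10 * length + 100):
        s = "".join(seq)
        pos = s.find("ATG")
        if pos < 0:
            pos = s.find("CAT")
        if pos < 0:
            break
        seq[pos + 1] = rng.choice([b for b in "CG"])
    s = "".join(seq)
    if "ATG" in s or "CAT" in s:
        raise RuntimeError("failed to scrub segment")
    if any(s.startswith(p) for p in forbid_start) or any(
        s.endswith(p) for p in forbid_end
    ):
        head = "GG" if any(s.startswith(p) for p in forbid_start) else s[:2]
        tail = "GG" if any(s.endswith(p) for p in forbid_end) else s[-2:]
        s = head + s[2:-2] + tail
    return s


def _tandem_unit(rng, unit_length: int, gc: float) -> str:
    for _ in range(1000):
        unit = _safe_segment(rng, unit_length, gc)
        doubled = unit + unit
        if "ATG" in doubled or "CAT" in doubled:
            continue
        if unit.startswith(("TG", "AT")) or unit[0] in "CG":
            continue
        # flanking context is cassette (ends ...A / starts G...); these
        # guards stop a rotated register of the array scoring equally
        if unit[-1] == "A":
            continue
        if len(set(unit)) < 2:
            continue
        return unit
    raise RuntimeError("could not sample a safe tandem unit")


def _ir_arm(rng, length: int, gc: float) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    for _ in range(1000):
        arm = _safe_segment(rng, length, gc)
        rc = arm.translate(comp)[::-1]
        if "ATG" in arm or "CAT" in arm or "ATG" in rc or "CAT" in rc:
            continue
        if arm.startswith("TG") or rc.startswith("TG"):
            continue
        return arm
    raise RuntimeError("could not sample a safe inverted-repeat arm")


def _pad_to_codon(parts_len: int) -> str:
    return "C" * ((3 - parts_len % 3) % 3)


def generate_viral_genome(
    n_orfs: int = 10,
    gc: float = 0.52,
    dr_spec: Sequence[Mapping] | None = None,
    ir_spec: Sequence[Mapping] | None = None,
    seed=0,
    orf_codon_range: tuple[int, int] = (150, 250),
    genome_id: str = "synthetic_virus",
):
    """Circular viral genome with recorded ORFs and repeat implants.

    ``dr_spec``: dicts with ``unit_length`` and ``copies``;
    ``ir_spec``: dicts with ``arm_length``, ``identity`` and ``gap``
    (gap given in spacer periods of 42 bp).  Returns
    ``(SequenceRecord, annotations, cds_by_orf, proteins_by_orf)``;
    the truth annotations use kinds ``orf`` and ``repeat``.
    """
    rng = _rng(seed)
    dr_spec = list(dr_spec or ())
    ir_spec = list(ir_spec or ())
    parts: list[str] = []
    annotations: list[AnnotationRecord] = []
    cds: dict[str, str] = {}

    def pos() -> int:
        return sum(len(p) for p in parts)

    parts.append(_spacer(rng, 2, gc))
    for i in range(1, n_orfs + 1):
        n_codons = int(rng.integers(orf_codon_range[0], orf_codon_range[1] + 1))
        cassette = CASSETTES[1 + (i - 1) % (len(CASSETTES) - 1)]
        orf_seq = _orf_sequence(rng, n_codons, gc, cassette)
        start = pos() + 1
        parts.append(orf_seq)
        end = pos()
        oid = f"orf{i:02d}"
        cds[oid] = orf_seq
        annotations.append(
            AnnotationRecord(genome_id, start, end, "+", "orf", {"ID": oid})
        )
        parts.append(_spacer(rng, 2, gc))

    for j, spec in enumerate(dr_spec, 1):
        u, k = int(spec["unit_length"]), int(spec["copies"])
        unit = _tandem_unit(rng, u, gc)
        array = unit * k
        start = pos() + 1
        parts.append(array)
        end = pos()
        parts.append(_pad_to_codon(pos()))
        parts.append(CASSETTE)
        parts.append(_spacer(rng, 1, gc))
        annotations.append(
            AnnotationRecord(
                genome_id, start, end, "+", "repeat",
                {"ID": f"dr{j}", "repeat_kind": "tandem_direct",
                 "unit_length": str(u), "copies": str(k)},
            )
        )

    comp = str.maketrans("ACGT", "TGCA")
    for j, spec in enumerate(ir_spec, 1):
        arm_len = int(spec["arm_length"])
        identity = float(spec.get("identity", 1.0))
        gap_periods = int(spec.get("gap", 2))
        arm1 = _ir_arm(rng, arm_len, gc)
        arm2 = list(arm1.translate(comp)[::-1])
        n_mut = round((1 - identity) * arm_len)
        if n_mut:
            margin = 15
            sites = rng.choice(np.arange(margin, arm_len - margin),
                               size=n_mut, replace=False)
            for site in sites:
                for base in rng.permutation(list("ACGT")):
                    if base == arm2[site]:
                        continue
                    trial = arm2.copy()
                    trial[site] = base
                    t = "".join(trial)
                    if "ATG" not in t and "CAT" not in t:
                        arm2 = trial
                        break
        arm2 = "".join(arm2)
        a1_start = pos() + 1
        parts.append(arm1)
        a1_end = pos()
        parts.append(_pad_to_codon(pos()))
        parts.append(CASSETTE)
        parts.append(_spacer(rng, gap_periods, gc))
        a2_start = pos() + 1
        parts.append(arm2)
        a2_end = pos()
        parts.append(_pad_to_codon(pos()))
        parts.append(CASSETTE)
        parts.append(_spacer(rng, 1, gc))
        annotations.append(
            AnnotationRecord(
                genome_id, a1_start, a2_end, "+", "repeat",
                {"ID": f"ir{j}", "repeat_kind": "inverted",
                 "start1": str(a1_start), "end1": str(a1_end),
                 "start2": str(a2_start), "end2": str(a2_end),
                 "identity": f"{(arm_len - n_mut) / arm_len:.4f}"},
            )
        )

    parts.append(_spacer(rng, 2, gc))
    seq = "".join(parts)
    assert len(seq) % 3 == 0
    record = SequenceRecord(genome_id, seq, topology="circular")
    proteins = {oid: translate_frame(c, 0)[:-1] for oid, c in cds.items()}
    logger.info("generate_viral_genome: %d bp, %d ORFs, %d repeat implants",
                len(seq), n_orfs, len(dr_spec) + len(ir_spec))
    return record, annotations, cds, proteins


# ---------------------------------------------------------------------------
# Evidence-profiled EVE implants
# ---------------------------------------------------------------------------

SCAFFOLD_EVIDENCE = ("depth_comparable", "eukaryotic_gene_on_scaffold",
                    "te_on_scaffold", "gc_similar",
                    "scaffold_exceeds_viral_size")

HOST_GC = 0.38
VIRAL_GC = 0.52
DISSIMILAR_GC = 0.50
HOST_DEPTH = 30.0
OUTLIER_DEPTH = 300.0
SHORT_SCAFFOLD = 30_000
LONG_SCAFFOLD = 504_000

# Inter-fragment gaps and fragment guards are runs of N (as in real
# assembly gaps): every codon containing N translates to X, which never
# scores positively, so translated alignments terminate exactly at the
# implanted fragment boundaries and recorded gap widths are exact.
_GAP_FILL = "N" * 120
_GUARD = "N" * 12


@dataclass
class EveProfile:
    """Recipe for one implanted element and its scaffold-level evidence."""

    name: str
    species: str = "species_1"
    gene: Optional[str] = None
    fragment_fractions: tuple = (0.9,)
    gaps_bp: tuple = ()
    stops_per_fragment: tuple = (0,)
    substitution_rate: float = 0.02
    depth_comparable: bool = False
    eukaryotic_gene_on_scaffold: bool = False
    te_on_scaffold: bool = False
    gc_similar: bool = True
    scaffold_exceeds_viral_size: bool = False

    def __post_init__(self) -> None:
        n = len(self.fragment_fractions)
        if len(self.gaps_bp) != n - 1:
            raise ValueError(f"{self.name}: need {n - 1} gaps for {n} fragments")
        if len(self.stops_per_fragment) != n:
            raise ValueError(f"{self.name}: stops_per_fragment length mismatch")
        if any(g % 3 == 0 for g in self.gaps_bp):
            raise ValueError(
                f"{self.name}: gaps must not be multiples of 3 (frame-distinct "
                "fragments keep translated hits separable)"
            )
        if sum(self.fragment_fractions) > 0.95:
            raise ValueError(f"{self.name}: fragment fractions exceed the gene")
        if any(f < 0.25 for f in self.fragment_fractions):
            raise ValueError(f"{self.name}: fragments below 25% query coverage")

    def expected_loci(self, merge_gap_bp: int = 10,
                      weights: Mapping[str, int] | None = None) -> list[dict]:
        """Expected merged loci with their stop counts, points and class."""
        weights = dict(DEFAULT_SCORE_WEIGHTS if weights is None else weights)
        groups: list[list[int]] = [[0]]
        for i, gap in enumerate(self.gaps_bp):
            if gap <= merge_gap_bp:
                groups[-1].append(i + 1)
            else:
                groups.append([i + 1])
        out = []
        for group in groups:
            stop_count = sum(self.stops_per_fragment[i] for i in group)
            points = (weights["premature_stop"] if stop_count >= 1 else 0) + sum(
                weights[name] for name in SCAFFOLD_EVIDENCE if getattr(self, name)
            )
            out.append(
                {
                    "fragments": group,
                    "stop_count": stop_count,
                    "points": points,
                    "confidence": classify_points(points),
                }
            )
        return out


@dataclass
class ImplantedElement:
    """Truth record for one implanted element."""

    element_id: str
    scaffold_id: str
    gene_id: str
    species: str
    fragments: list  # (start, end) 1-based inclusive, in order
    gaps_bp: tuple
    stops_per_fragment: tuple
    profile: EveProfile
    expected_loci: list


@dataclass
class SyntheticTruthSet:
    """Everything a pipeline run needs, plus the expected outcome."""

    scaffolds: list
    annotations: list
    depth_table: DepthTable
    elements: list
    species_of_scaffold: dict
    background_scaffold_ids: list
    viral_genome: Optional[SequenceRecord]
    viral_annotations: list
    viral_cds: dict
    viral_proteins: dict
    config: RunConfig

    def scaffold_map(self) -> dict:
        return {s.id: s for s in self.scaffolds}

    def expected_census(self, threshold_class: str = "high") -> dict:
        rank = {"low": 0, "medium": 1, "high": 2}
        per_class = {"high": 0, "medium": 0, "low": 0}
        presence: dict[str, set] = {}
        n = 0
        for el in self.elements:
            for locus in el.expected_loci:
                n += 1
                per_class[locus["confidence"]] += 1
                if rank[locus["confidence"]] >= rank[threshold_class]:
                    presence.setdefault(el.species, set()).add(el.gene_id)
        genes = sorted({g for s in presence.values() for g in s})
        matrix = {
            sp: {g: g in present for g in genes}
            for sp, present in sorted(presence.items())
        }
        return {
            "n_candidates": n,
            "per_class": per_class,
            "n_meeting_threshold": sum(
                1
                for el in self.elements
                for locus in el.expected_loci
                if rank[locus["confidence"]] >= rank[threshold_class]
            ),
            "threshold_class": threshold_class,
            "presence_matrix": matrix,
        }


def _degrade_fragment(rng, codons: list[str], sub_rate: float,
                      n_stops: int) -> tuple[list[str], int]:
    """Apply third-party-position-safe substitutions and inject TAA stop
    codons at interior positions; returns (codons, realized stops)."""
    n = len(codons)
    interior = list(range(3, n - 3))
    stop_sites: list[int] = []
    if n_stops:
        if len(interior) < n_stops:
            raise ValueError("fragment too short for requested stop injections")
        stop_sites = sorted(
            int(i) for i in rng.choice(interior, size=n_stops, replace=False)
        )
    allowed = [i for i in range(2, n - 2) if i not in stop_sites]
    n_sub = round(sub_rate * 3 * n)
    if n_sub and allowed:
        sites = rng.choice(allowed, size=min(n_sub, len(allowed)), replace=False)
        for site in sites:
            codon = codons[site]
            for _ in range(10):
                p = int(rng.integers(3))
                base = "ACGT"[int(rng.integers(4))]
                if base == codon[p]:
                    continue
                trial = codon[:p] + base + codon[p + 1 :]
                if trial not in STOP_CODONS:
                    codon = trial
                    break
            codons[site] = codon
    for site in stop_sites:
        codons[site] = "TAA"
    return codons, len(stop_sites)


def implant_eves(
    host_scaffolds: Sequence[SequenceRecord],
    viral_cds: Mapping[str, str],
    profiles: Sequence[EveProfile],
    seed=0,
    config: RunConfig | None = None,
) -> SyntheticTruthSet:
    """Implant degraded viral gene copies into host scaffolds, one
    element per scaffold, realizing each profile's evidence exactly.

    A profile is unsatisfiable (error) when its scaffold cannot realize
    the requested GC or length evidence.  Annotations and depth entries
    are arranged so every scaffold-level evidence boolean holds exactly
    as requested; expected per-locus points and classes are derived from
    the profile via the default scoring weights.
    """
    config = config or RunConfig()
    if len(host_scaffolds) < len(profiles):
        raise ValueError("need one host scaffold per profile")
    rng = _rng(seed)
    gene_ids = sorted(viral_cds)
    scaffolds: list[SequenceRecord] = []
    annotations: list[AnnotationRecord] = []
    depth = DepthTable()
    elements: list[ImplantedElement] = []
    species_map: dict[str, str] = {}

    from .features import gc_content

    for idx, (profile, host) in enumerate(zip(profiles, host_scaffolds), 1):
        sid = host.id
        host_gc = gc_content(host)
        wants_similar = profile.gc_similar
        if wants_similar and abs(host_gc - HOST_GC) > 0.02:
            raise ValueError(f"{profile.name}: scaffold GC {host_gc:.3f} cannot "
                             "realize gc_similar=True")
        if not wants_similar and abs(host_gc - HOST_GC) <= config.gc_similarity_delta:
            raise ValueError(f"{profile.name}: scaffold GC {host_gc:.3f} cannot "
                             "realize gc_similar=False")
        if profile.scaffold_exceeds_viral_size and len(host.seq) <= config.long_scaffold_bp:
            raise ValueError(
                f"{profile.name}: long-scaffold evidence on a "
                f"{len(host.seq)} bp scaffold is unsatisfiable"
            )
        if not profile.scaffold_exceeds_viral_size and len(host.seq) > config.long_scaffold_bp:
            raise ValueError(f"{profile.name}: scaffold too long for "
                             "scaffold_exceeds_viral_size=False")

        gene = profile.gene or gene_ids[idx % len(gene_ids)]
        cds = viral_cds[gene]
        body = cds[: len(cds) - 3]  # drop the terminal stop codon
        codons = [body[i : i + 3] for i in range(0, len(body), 3)]
        n_codons = len(codons)

        # consecutive codon-aligned fragments from the start of the gene
        frag_codons: list[list[str]] = []
        cursor = 0
        for frac, n_stops in zip(profile.fragment_fractions,
                                 profile.stops_per_fragment):
            size = int(round(frac * n_codons))
            chunk = codons[cursor : cursor + size]
            chunk, _ = _degrade_fragment(rng, list(chunk),
                                         profile.substitution_rate, n_stops)
            frag_codons.append(chunk)
            cursor += size

        insert_at = int(rng.integers(len(host.seq) // 4, len(host.seq) // 2))
        pieces = [host.seq[:insert_at], _GUARD]
        fragments: list[tuple[int, int]] = []
        cur = insert_at + len(_GUARD)
        for i, chunk in enumerate(frag_codons):
            frag_seq = "".join(chunk)
            fragments.append((cur + 1, cur + len(frag_seq)))
            pieces.append(frag_seq)
            cur += len(frag_seq)
            if i < len(profile.gaps_bp):
                g = profile.gaps_bp[i]
                pieces.append(_GAP_FILL[:g])
                cur += g
        pieces.append(_GUARD)
        pieces.append(host.seq[insert_at:])
        scaffold = SequenceRecord(sid, "".join(pieces))
        scaffolds.append(scaffold)
        species_map[sid] = profile.species

        if profile.eukaryotic_gene_on_scaffold:
            annotations.append(
                AnnotationRecord(sid, 1000, 3000, "+", "gene",
                                 {"ID": f"{sid}_gene1", "taxon": "insect"})
            )
        if profile.te_on_scaffold:
            annotations.append(
                AnnotationRecord(sid, 5000, 5600, "+", "transposable_element",
                                 {"ID": f"{sid}_te1"})
            )
        depth[sid] = HOST_DEPTH + 5 if profile.depth_comparable else OUTLIER_DEPTH

        elements.append(
            ImplantedElement(
                element_id=f"eve{idx:03d}",
                scaffold_id=sid,
                gene_id=gene,
                species=profile.species,
                fragments=fragments,
                gaps_bp=profile.gaps_bp,
                stops_per_fragment=profile.stops_per_fragment,
                profile=profile,
                expected_loci=profile.expected_loci(
                    config.merge_gap_bp, config.score_weights
                ),
            )
        )

    # background host scaffolds: insect gene, no implant, median depth
    background_ids = []
    for i, d in enumerate([28.0, 29.0, 30.0, 31.0, 32.0], 1):
        sid = f"host_bg_{i}"
        background_ids.append(sid)
        scaffolds.append(generate_host_scaffold(20_000, HOST_GC, rng, sid))
        annotations.append(
            AnnotationRecord(sid, 2000, 4000, "+", "gene",
                             {"ID": f"{sid}_gene1", "taxon": "insect"})
        )
        depth[sid] = d
        species_map[sid] = "background"

    proteins = {g: translate_frame(c, 0)[:-1] for g, c in viral_cds.items()}
    logger.info("implant_eves: %d elements on %d scaffolds", len(elements),
                len(scaffolds))
    return SyntheticTruthSet(
        scaffolds=scaffolds,
        annotations=annotations,
        depth_table=depth,
        elements=elements,
        species_of_scaffold=species_map,
        background_scaffold_ids=background_ids,
        viral_genome=None,
        viral_annotations=[],
        viral_cds=dict(viral_cds),
        viral_proteins=proteins,
        config=config,
    )


def default_cohort_profiles() -> list[EveProfile]:
    """A 50-element cohort exercising every class boundary (0, 2, 3, 4,
    5, 6, 7 points) and both merge outcomes (gap <= 10 and gap > 10)."""
    species = ["ant_sp1", "ant_sp2", "ant_sp3"]
    templates = [
        # (count, kwargs)
        (4, dict(name="bare", stops_per_fragment=(0,), gc_similar=False)),
        (6, dict(name="stops_only", stops_per_fragment=(2,), gc_similar=False)),
        (4, dict(name="depth_gene", stops_per_fragment=(0,), gc_similar=False,
                 depth_comparable=True, eukaryotic_gene_on_scaffold=True)),
        (6, dict(name="stops_depth", stops_per_fragment=(1,), gc_similar=False,
                 depth_comparable=True)),
        (6, dict(name="stops_depth_gene", stops_per_fragment=(1,),
                 gc_similar=False, depth_comparable=True,
                 eukaryotic_gene_on_scaffold=True)),
        (6, dict(name="five_points", stops_per_fragment=(2,), gc_similar=False,
                 depth_comparable=True, eukaryotic_gene_on_scaffold=True,
                 te_on_scaffold=True)),
        (4, dict(name="six_points", stops_per_fragment=(1,), gc_similar=True,
                 depth_comparable=True, eukaryotic_gene_on_scaffold=True,
                 te_on_scaffold=True)),
        (2, dict(name="seven_points", stops_per_fragment=(1,), gc_similar=True,
                 depth_comparable=True, eukaryotic_gene_on_scaffold=True,
                 te_on_scaffold=True, scaffold_exceeds_viral_size=True)),
        (6, dict(name="split_fragments", fragment_fractions=(0.4, 0.4),
                 gaps_bp=(19,), stops_per_fragment=(1, 1), gc_similar=False,
                 depth_comparable=True, eukaryotic_gene_on_scaffold=True)),
        (6, dict(name="merged_fragments", fragment_fractions=(0.4, 0.4),
                 gaps_bp=(5,), stops_per_fragment=(1, 0), gc_similar=False,
                 eukaryotic_gene_on_scaffold=True, te_on_scaffold=True)),
    ]
    profiles = []
    i = 0
    for count, kwargs in templates:
        for rep in range(1, count + 1):
            profiles.append(
                EveProfile(species=species[i % len(species)],
                           **{**kwargs, "name": f"{kwargs['name']}_{rep}"})
            )
            i += 1
    return profiles


def generate_cohort(profiles: Sequence[EveProfile] | None = None, seed=0,
                    config: RunConfig | None = None,
                    n_viral_orfs: int = 8) -> SyntheticTruthSet:
    """Build a full ground-truthed screening cohort.

    Generates a viral genome, host scaffolds matching every profile's
    GC/length evidence, and the implants; the returned truth set carries
    the viral genome, proteome, and all expected outcomes.
    """
    config = config or RunConfig()
    profiles = list(profiles) if profiles is not None else default_cohort_profiles()
    genome, v_anns, cds, proteins = generate_viral_genome(
        n_orfs=n_viral_orfs, gc=VIRAL_GC,
        dr_spec=[{"unit_length": 12, "copies": 10}],
        ir_spec=[{"arm_length": 150, "identity": 0.98, "gap": 2}],
        seed=_rng((seed, 1)),
    )
    hosts = []
    for i, profile in enumerate(profiles, 1):
        length = (LONG_SCAFFOLD if profile.scaffold_exceeds_viral_size
                  else SHORT_SCAFFOLD)
        gc = HOST_GC if profile.gc_similar else DISSIMILAR_GC
        hosts.append(
            generate_host_scaffold(length, gc, _rng((seed, 100 + i)),
                                   f"scaffold_{i:03d}")
        )
    truth = implant_eves(hosts, cds, profiles, seed=_rng((seed, 2)),
                         config=config)
    truth.viral_genome = genome
    truth.viral_annotations = v_anns
    return truth


# ---------------------------------------------------------------------------
# Codon evolution under a target omega
# ---------------------------------------------------------------------------

def evolve_codons(cds: str, omega: float, t: float, seed=0):
    """Evolve a coding sequence under relative nonsynonymous rate omega.

    Proposal events are Poisson with neutral-scale expectation ``t``
    substitutions per codon; each proposal mutates one random codon
    position to a random alternative base, is rejected if it creates a
    stop, and is accepted with relative probability omega (nonsynonymous)
    vs 1 (synonymous).  Returns ``(mutated_cds, counts)`` where counts
    records the true accepted synonymous/nonsynonymous substitutions.
    """
    from .evolution import _AA, STOP_CODONS as _STOPS

    if omega < 0:
        raise ValueError("omega must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS and i + 1 < len(codons):
            raise ValueError(f"internal stop codon at codon {i + 1}")
    evolvable = [i for i, c in enumerate(codons) if c not in _STOPS]
    rng = _rng(seed)
    scale = max(1.0, omega)
    n_events = int(rng.poisson(t * len(evolvable) * scale))
    n_syn = n_nonsyn = 0
    for _ in range(n_events):
        i = evolvable[int(rng.integers(len(evolvable)))]
        codon = codons[i]
        p = int(rng.integers(3))
        alternatives = [b for b in _BASES if b != codon[p]]
        base = alternatives[int(rng.integers(3))]
        trial = codon[:p] + base + codon[p + 1 :]
        if trial in _STOPS:
            continue
        synonymous = _AA[trial] == _AA[codon]
        accept_p = (1.0 if synonymous else omega) / scale
        if rng.random() < accept_p:
            codons[i] = trial
            if synonymous:
                n_syn += 1
            else:
                n_nonsyn += 1
    return "".join(codons), {"n_syn": n_syn, "n_nonsyn": n_nonsyn}
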