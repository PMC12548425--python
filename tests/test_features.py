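"""Genome feature statistics against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evescreen.features import (STOP_CODONS, coding_density,
                                find_inverted_repeats, find_orfs,
                                find_tandem_repeats, gc_content, OrfCall,
                                rescore_tandem_array)
from evescreen.io import SequenceRecord, reverse_complement

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


def random_seq(n, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATATAT", 0.0), ("ACGT", 0.5), ("ACGTNNNN", 0.5),
    ])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            gc_content("NNNN")

    def test_window_track_tiles_sequence(self):
        overall, track = gc_content("GGGGAAAACC", window=4)
        assert track == [1.0, 0.0, 1.0]
        assert overall == pytest.approx(0.6)

    @settings(max_examples=50, derandomize=True)
    @given(dna)
    def test_reverse_complement_invariance(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def brute_force_orfs(seq, min_length_nt):
    """Independent enumerator: every ATG walks to its first in-frame stop;
    keep the earliest ATG per (frame, strand, stop)."""
    L = len(seq)
    found = {}
    for strand in "+-":
        work = seq if strand == "+" else reverse_complement(seq)
        for i in range(L - 2):
            if work[i:i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= L and work[j:j + 3] not in STOP_CODONS:
                j += 3
            if j + 3 > L:
                continue  # no stop: truncated, not reported by default
            key = (strand, i % 3, j)
            if key not in found or i < found[key]:
                found[key] = i
    out = set()
    for (strand, _frame, j), i in found.items():
        nt_len = j + 3 - i
        if nt_len < min_length_nt:
            continue
        if strand == "+":
            out.add((i + 1, j + 3, "+"))
        else:
            out.add((L - (j + 3) + 1, L - i, "-"))
    return out


class TestFindOrfs:
    def test_minimal_orf(self):
        (orf,) = find_orfs("ATGAAATAA", min_length_nt=9)
        assert (orf.start, orf.end, orf.strand, orf.length_aa) == (1, 9, "+", 2)

    def test_reverse_strand_mirrored(self):
        (orf,) = find_orfs(reverse_complement("ATGAAATAA"), min_length_nt=9)
        assert (orf.start, orf.end, orf.strand) == (1, 9, "-")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_10kb(self, seed):
        seq = random_seq(10_000, seed)
        ours = {(o.start, o.end, o.strand) for o in find_orfs(seq, 150)}
        assert ours == brute_force_orfs(seq, 150)

    def test_nested_atg_not_reported(self):
        # two ATGs share a stop: only the maximal span is reported
        seq = "ATGATGAAATAA"
        orfs = find_orfs(seq, min_length_nt=9)
        assert [(o.start, o.end) for o in orfs] == [(1, 12)]

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_strand_mirror_property(self, seed):
        seq = random_seq(2_000, seed)
        fwd = {(o.start, o.end, o.strand) for o in find_orfs(seq, 150)}
        L = len(seq)
        rev = {
            (L - e + 1, L - s + 1, "-" if strand == "+" else "+")
            for s, e, strand in (
                (o.start, o.end, o.strand)
                for o in find_orfs(reverse_complement(seq), 150)
            )
        }
        assert fwd == rev

    def test_circular_rotation_invariance(self, viral_genome):
        record, annotations, _, _ = viral_genome
        L = len(record.seq)
        k = 1234
        rotated = SequenceRecord(record.id, record.seq[k:] + record.seq[:k],
                                 topology="circular")
        base = {((o.start - 1 - k) % L, o.length_aa, o.strand)
                for o in find_orfs(record, 150)}
        rot = {((o.start - 1) % L, o.length_aa, o.strand)
               for o in find_orfs(rotated, 150)}
        assert base == rot

    def test_recovers_implanted_orfs_exactly(self, viral_genome):
        record, annotations, _, _ = viral_genome
        truth = {(a.start, a.end) for a in annotations if a.kind == "orf"}
        found = {(o.start, o.end) for o in find_orfs(record, 150)}
        assert found == truth


# ---------------------------------------------------------------------------
# Coding density
# ---------------------------------------------------------------------------

class TestCodingDensity:
    def test_full_coverage_both_modes(self):
        orf = OrfCall("g", 1, 300, "+", 99)
        assert coding_density([orf], 300, "sum") == pytest.approx(100.0)
        assert coding_density([orf], 300, "union") == pytest.approx(100.0)

    def test_overlap_double_counted_in_sum_only(self):
        orfs = [OrfCall("g", 1, 300, "+", 99), OrfCall("g", 1, 300, "-", 99)]
        assert coding_density(orfs, 1000, "sum") == pytest.approx(60.0)
        assert coding_density(orfs, 1000, "union") == pytest.approx(30.0)

    def test_union_never_exceeds_sum(self, viral_genome):
        record, _, _, _ = viral_genome
        orfs = find_orfs(record, 150)
        union = coding_density(orfs, len(record.seq), "union")
        total = coding_density(orfs, len(record.seq), "sum")
        assert union <= total + 1e-9

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            coding_density([], 0)


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def brute_force_tandem(seq, min_score, min_unit, max_unit):
    """Exhaustive consensus-scored arrays over all (start, unit, copies)."""
    L = len(seq)
    candidates = []
    for u in range(min_unit, max_unit + 1):
        for i in range(L - 2 * u + 1):
            best = None
            k = 2
            while i + k * u <= L:
                score = rescore_tandem_array(seq, i + 1, u, k)
                if best is None or score > best[1]:
                    best = (k, score)
                k += 1
            if best and best[1] >= min_score:
                candidates.append((i, u, best[0], best[1]))
    # same collapse rule as the implementation
    kept, out = [], []
    for i, u, k, score in sorted(candidates,
                                 key=lambda c: (-c[3], -(c[2] * c[1]), c[0], c[1])):
        lo, hi = i, i + k * u - 1
        if any(lo <= e and b <= hi for b, e in kept):
            continue
        kept.append((lo, hi))
        out.append((lo + 1, hi + 1, u, k, score))
    return sorted(out)


class TestTandemRepeats:
    def test_perfect_array_score(self):
        seq = "ACGTA" * 60
        (rep,) = find_tandem_repeats(seq, min_score=100, min_unit=2, max_unit=10)
        assert (rep.unit_length, rep.copies, rep.score) == (5, 60, 300)

    def test_substitutions_cost_two_points_each(self):
        rng = np.random.default_rng(0)
        seq = list("ACGTA" * 60)
        sites = rng.choice(len(seq), size=10, replace=False)
        for site in sites:
            current = seq[site]
            seq[site] = {"A": "C", "C": "A", "G": "T", "T": "G"}[current]
        (rep,) = find_tandem_repeats("".join(seq), 100, 2, 10)
        assert rep.score == 300 - 2 * 10
        assert rescore_tandem_array("".join(seq), rep.start, rep.unit_length,
                                    rep.copies) == rep.score

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        # implant one degraded array so the comparison is not vacuous
        seq = seq[:200] + "ACGGTT" * 25 + seq[200:]
        ours = sorted(
            (r.start, r.end, r.unit_length, r.copies, r.score)
            for r in find_tandem_repeats(seq, 100, 2, 8)
        )
        assert ours == brute_force_tandem(seq, 100, 2, 8)

    def test_reported_arrays_rescore_above_cutoff(self, viral_genome):
        record, _, _, _ = viral_genome
        for rep in find_tandem_repeats(record.seq, 100):
            assert rescore_tandem_array(record.seq, rep.start, rep.unit_length,
                                        rep.copies) >= 100

    def test_recovers_implanted_array(self, viral_genome):
        record, annotations, _, _ = viral_genome
        truth = [a for a in annotations
                 if a.attributes.get("repeat_kind") == "tandem_direct"]
        found = find_tandem_repeats(record.seq, 100)
        assert [(r.start, r.end, r.unit_length, r.copies) for r in found] == [
            (a.start, a.end, int(a.attributes["unit_length"]),
             int(a.attributes["copies"])) for a in truth
        ]
        assert all(r.score == r.unit_length * r.copies for r in found)


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def brute_force_no_inverted_pair(seq, arm_len, min_identity):
    """Oracle: verify no window pair (a, b) of length ``arm_len`` pairs the
    sequence with its reverse complement at >= min_identity.  Any longer
    qualifying arm would contain a qualifying window, so emptiness here
    implies emptiness overall."""
    rc = reverse_complement(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    L = len(seq)
    need = int(np.ceil(min_identity * arm_len))
    for d in range(-(L - arm_len), L - arm_len + 1):
        if d >= 0:
            m = (a[d:] == b[: L - d]).astype(np.int32)
        else:
            m = (a[: L + d] == b[-d:]).astype(np.int32)
        if len(m) < arm_len:
            continue
        window = np.convolve(m, np.ones(arm_len, dtype=np.int32), "valid")
        if (window >= need).any():
            return False
    return True


class TestInvertedRepeats:
    def _implant(self, seed, n_mut=0):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list("ACGT"), size=2000)))
        arm = "".join(rng.choice(list("ACGT"), size=300))
        arm2 = list(reverse_complement(arm))
        for site in rng.choice(np.arange(20, 280), size=n_mut, replace=False):
            current = arm2[site]
            arm2[site] = {"A": "C", "C": "A", "G": "T", "T": "G"}[current]
        p, q = 300, 1200
        seq[p : p + 300] = arm
        seq[q : q + 300] = arm2
        # guard bases: equal bases are never complementary, so extension
        # stops exactly at the implanted arm boundaries
        seq[p - 1] = seq[q + 300] = "A"
        seq[p + 300] = seq[q - 1] = "G"
        return "".join(seq), p + 1, q + 1

    def test_exact_pair_recovered(self):
        seq, p, q = self._implant(5)
        (rep,) = find_inverted_repeats(seq, 100, 0.9)
        assert (rep.start1, rep.end1, rep.start2, rep.end2) == (p, p + 299, q, q + 299)
        assert rep.identity == pytest.approx(1.0)

    def test_identity_with_six_mismatches(self):
        seq, p, q = self._implant(6, n_mut=6)
        (rep,) = find_inverted_repeats(seq, 100, 0.9)
        assert rep.identity == pytest.approx(294 / 300)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_random_sequence_empty_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        assert find_inverted_repeats(seq, 100, 0.9) == []
        assert brute_force_no_inverted_pair(seq, 100, 0.9)

    def test_recovers_implanted_pair_in_viral_genome(self, viral_genome):
        record, annotations, _, _ = viral_genome
        truth = [a for a in annotations
                 if a.attributes.get("repeat_kind") == "inverted"]
        found = find_inverted_repeats(record.seq, 100, 0.9)
        assert [(r.start1, r.end1, r.start2, r.end2) for r in found] == [
            (int(a.attributes["start1"]), int(a.attributes["end1"]),
             int(a.attributes["start2"]), int(a.attributes["end2"]))
            for a in truth
        ]
        assert found[0].identity == pytest.approx(
            float(truth[0].attributes["identity"]), abs=1e-4
        )
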