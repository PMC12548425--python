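# Methods

## The screening model

The pipeline treats an endogenous viral element (EVE) as a genomic
interval of a host scaffold with translated-protein homology to a viral
proteome, supported by evidence that the interval sits in a genuine host
genomic context rather than in co-assembled exogenous virus or
contamination. The screen is deliberately simple and auditable:

1. **Translated search.** Each viral protein is compared against all six
   reading frames of every scaffold. The built-in search seeds on exact
   4-mer amino-acid matches, extends ungapped with X-drop termination
   (drop 16), and rescores surviving HSPs by local affine-gap alignment
   (BLOSUM62, gap open 11 / extend 1) in a window around the HSP.
   E-values use the Karlin–Altschul formula E = K·m·n·e^(−λS) with the
   published ungapped BLOSUM62 constants (λ = 0.3176, K = 0.134), where n
   is the total number of translated residues searched. These e-values
   are approximate — adequate for the strict 1e-5 screen, not a
   replacement for BLAST statistics. Externally produced 12-column
   tabular hits can be substituted at any point, and exact-value filter
   tests use supplied tabular hits.

   One deliberate deviation from the stock matrix: the `X` row of
   BLOSUM62 is set to −4. Stock BLOSUM62 scores X against A/S/T as 0,
   which lets alignments drift across assembly-gap codons (translated N
   runs) at no cost; here an unknown codon terminates an alignment just
   as a stop does.

2. **Filtering.** A hit survives iff e-value < 1e-5 (strict) and query
   coverage > 0.20 (strict). Survivor counts are logged and returned:
   screen attrition is a first-class output.

3. **Merging.** Surviving hits on a scaffold merge transitively whenever
   the next hit starts within 10 bp of the running end. Merging ignores
   query identity and strand by default (a degraded viral gene often
   fragments across frames and queries); a config switch
   (`merge_same_query_only`) restricts it. "Within 10 bp" is read as
   `next.start − current.end ≤ merge_gap_bp`; the boundary is covered by
   tests on both sides via the config value.

4. **Evidence and scoring.** Six boolean features are evaluated per
   locus, each reported with the numeric value that produced it, then
   combined as a weighted sum (premature stops 2 points, the rest 1) and
   classified: high > 4, medium 3–4, low ≤ 2 — partitioning 0..7 as
   {0,1,2} / {3,4} / {5,6,7}.

   - *Premature stops*: each member hit's scaffold span is translated in
     its own frame; internal `*` are counted (a terminal stop is not
     premature). Subject gaps inside a member alignment would shift the
     downstream reading and are not corrected for; on the synthetic data
     alignments are effectively ungapped.
   - *Depth comparable*: locus-scaffold depth within a factor-2 band of
     the host median. "Comparable" is not quantified in the protocol this
     implements; the factor is exposed (`depth_comparable_factor`) and
     the raw depths are reported so users can re-threshold without
     rerunning.
   - *GC similar*: |scaffold GC − host mean GC| ≤ 0.05, same reasoning.
   - *Host background*: median depth and mean GC are computed from
     scaffolds that carry ≥ 1 insect-assigned gene and no candidate
     locus — a proxy for curated single-copy host scaffolds that needs no
     ortholog database. Insect assignment is an input flag on gene
     annotations, not computed locally.
   - *Long scaffold*: length > 500 kb, the upper size bound of known
     exogenous genomes in this virus class.
   - Missing evidence (e.g. no depth entry) scores 0 and is recorded as
     unavailable rather than imputed: conservative under an additive
     scheme.

   When one scaffold carries several loci, scaffold-level evidence is
   shared and only the stop count is per locus.

## Genome features

- **GC** ignores N in numerator and denominator; windows tile the
  sequence with a short final window.
- **ORFs** are maximal ATG-to-stop spans per frame (nested ATGs under the
  same stop are not reported separately; longest-ORF-per-stop rule). On
  circular sequences the scan runs on a tripled copy and reports each ORF
  once, with origin-wrapping flagged; rotation of a circular genome
  rotates coordinates and changes nothing else. The minimum length
  defaults to 150 nt (50 aa) — a conventional small-protein floor, since
  the protocol this follows does not state its threshold; printed ORF
  counts are sensitive to it, so it is config-exposed
  (`orf_min_length_nt`). Truncated ORFs at linear ends are reported only
  on request.
- **Coding density** is emitted in both readings: `sum` (total ORF bases
  over genome length, overlaps double-counted — the literal base-count
  ratio) and `union` (distinct covered positions). `union ≤ sum` always,
  with equality iff no ORFs overlap.
- **Tandem repeats** follow the etandem scoring convention: an array of k
  unit copies scores +1 per position matching the per-column consensus
  and −1 otherwise (perfect array: unit × copies). Arrays at different
  unit lengths that overlap collapse to the best score (ties: longer,
  then leftmost, then smallest unit — the minimal period wins).
  Exact etandem tie-breaking is not reproduced, so repeat counts on real
  genomes should be compared with tolerance.
- **Inverted repeats** seed on exact 12-mers between the sequence and its
  reverse complement and extend ungapped (+1/−3, X-drop 12) to the
  maximal-scoring extent; arm pairs need arm length ≥ 100, identity
  (matches/arm length) ≥ 0.90, non-overlapping arms. Overlapping
  candidates resolve greedily by identity × length.

## Selection (NG86)

The protocol's ML codon-model step is replaced by the closed-form
Nei–Gojobori (1986) counting method with Jukes–Cantor correction — a
documented approximation whose supported claim is the binary purifying
flag (ω < 1), not the exact ML ω. Details:

- Site counting averages over the three positions and three possible
  substitutions per position; substitutions creating stop codons count as
  nonsynonymous, so S + N = 3 × codons exactly.
- Difference counting enumerates all shortest substitution paths between
  differing codons, excludes paths through stop codons (standard NG86
  practice), and weights the rest equally; if every path is blocked, all
  paths are used with stop-crossing steps scored nonsynonymous. Path
  weighting is unweighted (no transition/transversion κ).
- Jukes–Cantor: d = −¾·ln(1 − 4p/3); p ≥ ¾ leaves the rate undefined and
  flagged (`dS_saturated`). ω is defined only when dS > 0. A single
  differing codon pair with nothing else aligned saturates pS and is
  flagged rather than forced.
- Gapped columns (whole-codon gaps only) are skipped.
- The implementation is cross-checked in the tests against an independent
  reference implementation and recovers simulated ω within ±0.15 at 300+
  codons.

Comparisons are pairwise (EVE versus viral homolog), matching how the
screen is used.

## Phylogeny and synteny

Trees are consumed, never inferred. Patristic distances are path sums
over user-supplied branch lengths (missing lengths are an explicit
error); matrices satisfy symmetry, zero diagonal and the four-point
condition, which the tests check on random trees against a
shortest-path oracle. Family summaries report min/max/mean per family
pair plus pooled within/between ranges; singleton families contribute no
within pairs and warn. RBH pairing requires mutual best bitscores with
deterministic tie-breaks (lower e-value, then lexicographic subject id).
Synteny ranks are 1-based indices in start-coordinate order with a
per-pair strand-agreement flag.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure each stage assumes,
with every expected outcome recorded:

- **Host scaffolds** are i.i.d. base sequences at a target GC (default
  background 0.38, versus 0.52 for viral material, so the GC criterion is
  exercised in both directions).
- **Viral genomes** are circular with non-overlapping ATG…stop ORFs and
  repeat implants at recorded coordinates. Exact ORF-set recovery is
  guaranteed *by construction*: ORF interiors and spacers are salted with
  15-nt codon-aligned "stop cassettes" carrying stop codons in both
  shifted forward frames and all three reverse frames, spacers carry
  frequent in-frame stops and end ATG-free, and repeat arms/units exclude
  ATG/CAT — so no reading frame outside the implanted ORFs stays open to
  the minimum length. Each synthetic gene uses a *distinct* cassette
  whose translation shares no amino-acid 4-mer with any other, so
  cassettes never make two synthetic genes spuriously homologous.
- **Implants** realize an evidence profile exactly: fragments are
  codon-aligned gene slices, degraded by stop-avoiding substitutions
  (default 2%) and injected TAA stops at recorded interior codons, placed
  with recorded inter-fragment gaps and flanked by N runs, on a scaffold
  whose length, GC, depth entry and gene/TE annotations realize the five
  scaffold-level booleans. Gaps avoid multiples of 3 so fragments sit in
  distinct frames and no single translated alignment can bridge them;
  gap values straddle the 10-bp merge rule (5 merges, 19 splits).
  Expected per-locus points and class are derived from the profile with
  the scoring weights and stored. The default 50-element cohort covers
  every class boundary (2, 3, 4, 5 points) and both merge outcomes.
- **Codon evolution** proposes Poisson(t·n·max(1,ω)) single-base events,
  rejects stop-creating ones, and accepts with relative probability ω
  (nonsynonymous) versus 1 (synonymous); t is the neutral-scale expected
  substitutions per codon, and true accepted counts are recorded.

What passing these tests does *not* show about real data: synthetic
scaffolds have no repeats, paralogs, introns or compositional
heterogeneity; degradation has no indels, so real frame-shifted EVEs will
fragment more than the synthetic ones; e-values are approximate; and the
stop-cassette scaffolding means synthetic proteins are not realistic
protein sequences. The screen's behavior on real assemblies should be
validated against external search tools at scale.

## Numerical and design choices

- Coordinates are 1-based inclusive at every external interface; N
  counts toward length, never toward GC or matches.
- Determinism: all generators are pure functions of their arguments
  including the seed; search output order is fixed (e-value, then
  coordinates); report files are byte-identical across runs.
- Translated alignments may legitimately overrun an implanted fragment's
  boundary by a residue or two when flanking sequence happens to score
  positively — exactly as production translated-search tools do. The
  end-to-end tests therefore assert the scored evidence (points, class,
  stop boolean) against truth, and assert exact injected stop counts at
  fragment level.
- ω-sweep conditions: 500 codons, 100 replicates, ω ∈ {0.1, 0.5, 1.0,
  2.0} at divergence t = 0.6. The divergence is chosen deep enough that
  counting noise does not dominate the ratio: at very shallow divergence
  the ordering of adjacent ω values is limited by information, not by the
  estimator.
- Problem sizes: the default test cohort is 50 elements on ~30 kb
  scaffolds (two >500 kb scaffolds for the length criterion), about
  2.6 Mb of sequence; oracle comparisons run on 0.5–10 kb inputs. These
  sizes make every oracle exhaustive while keeping the whole suite at
  about a minute.

## Known limitations

- The built-in search is a desk-scale tool: no composition-based
  statistics, no low-complexity (SEG) masking (config stub), no
  bit-for-bit BLAST compatibility. For 60-genome screens, generate hits
  with a production search tool and feed them in as tabular files.
- Back-validation of candidate loci against a comprehensive protein
  database (the "clearly aligns with viral sequences" confirmation step)
  requires that database and is represented only as an optional
  annotation column, never computed locally.
- The NG86 ω is a counting estimate; branch/site ML models are out of
  scope.
- Transcriptional-activity calling and re-identification of previously
  published EVE sets are out of scope; expression flags may be joined
  from an input table.
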