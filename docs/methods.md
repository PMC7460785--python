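# Methods

## Scope and model

zfpkit re-implements, as a reusable library, the standard genome-wide
survey workflow for the C2H2 zinc-finger family: regex-based motif
discovery on an annotated proteome, confirmation filtering, core-sequence
typing, architecture description, local-duplication detection from gene
order, physicochemical profiling and expression tiering. External
database scans (PROSITE/PFAM-style confirmation, BLAST homology), profile
HMM construction, phylogenetics and synteny detection are deliberately out
of scope; their *outputs* (a keep/drop verdict list, a WGD pair list) are
ingested instead.

## The scanner

The finger geometry X2-C-X(2,4)-C-X12-H-X(3,4,5)-H is expressed as two
regexes, one per Cys spacing: `.{2}C.{2}C.{12}H.{3,5}H` and
`.{2}C.{4}C.{12}H.{3,5}H`. Decisions that the geometry alone does not fix:

- **Quantifier semantics.** `published` mode uses Python `re.finditer`
  semantics — leftmost, non-overlapping, greedy inter-His gap (the longest
  of 3–5 that completes the match at an anchor). This mirrors the default
  behaviour of the scripting environment such scans are normally written
  in. `exhaustive` mode enumerates every satisfying window, validated
  character by character independently of the regex engine, and is the
  oracle superset used in tests.
- **Cross-pattern overlaps.** Where a Cys-gap-2 and a Cys-gap-4 call
  overlap, the gap-2 call is kept: C-X2-C is the canonical C2H2 geometry
  and one physical finger should yield one call. Both policies remain
  observable via `exhaustive`.
- **Leading wildcards.** The pattern demands two residues before the first
  Cys, so a Cys at position 0 or 1 of a protein cannot anchor a motif.
  This is faithful to the pattern as written, though biologically
  arbitrary; it is kept because changing it would change candidate counts.
- **Residue `X`** matches wildcard positions but never counts as Cys/His.

EAR sites use the two canonical repression-motif classes, `LxLxL` and
`DLNxxP`, evaluated independently per pattern with leftmost
non-overlapping matching, then merged. The pattern set is configurable; L
positions must be literal leucines.

## Classification rules

Precedence Q → QM → IDD → Z → C; each finger receives exactly one type.

- **Q**: core6 (the six residues ending at the first His) equals `QALGGH`.
  Subgroups are consensus classes of the three inter-His residues —
  Q1 `QNA`, Q2 `(K/R)AS`, Q3 `MR(R/K)`, Q4 `MN(I/V)`, Q5 `KR(C/S)` — and
  are defined only for a 3-residue inter-His gap; Q fingers with gaps of
  4–5, or a non-consensus triplet, are Q6.
- **QM** ("Q-modified"): Hamming distance 1–2 from `QALGG` over the five
  pre-His core positions (the sixth is structurally His). The subgroup
  label defaults to the mismatch signature (`P1:R` for `RALGGH`); a
  mapping from signatures to curated subgroup names can be loaded from the
  rules config.
- **IDD**: a 23-residue finger (Cys gap 2, His gap 3) whose first residue
  is Phe and which agrees with a per-position reference profile at ≥ 16 of
  23 positions. The packaged default profile is a **synthetic stand-in**
  constructed to have the formal properties of the INDETERMINATE-DOMAIN
  signature (23-mer, leading F, strong conservation); real analyses should
  build the profile from their own reference motifs with
  `build_idd_profile` (≥ 2 aligned 23-mers; majority consensus, ties
  alphabetical; frequency-1.0 positions flagged invariant).
- **Z**: conserved cores outside the above. The primary path matches core6
  against a signature table from the rules config; the packaged default
  table (Z1–Z8) is likewise a synthetic stand-in. When no table is given,
  a deterministic fallback clusters unassigned fingers by single-linkage
  on full-string identity (≥ 0.60, clusters of ≥ 2; labels ordered by
  smallest member protein id).
- **C**: the residual class.

All thresholds (`qm_max_mismatch`, `idd_min_matches`, the Z identity and
size cutoffs) live in `ClassifierRules` and in the `classify:` section of
a YAML rules file.

## Architecture

The tandem-array rule is *linker < 11 residues*, where the linker counts
residues strictly between two matched spans. Survey descriptions of such
arrays sometimes quote spacers "from zero to 11 residues", which
conflicts with a strict sub-11 rule; the operational "fewer than 11"
reading is used here, and the threshold is exposed
(`--tandem-max-linker`). Arrays are maximal runs under the chain relation,
hence disjoint, and monotone in the threshold.

Single-finger EAR arrangements are decided on feature midpoints:
finger-then-EAR, EAR-then-finger, finger between two EARs, two EARs one
side, `mixed` for three or more. An EAR lying inside a finger (as in the
five-finger repressor TRM1, whose fifth finger carries an `LKLHLK`) is
reported as a flagged overlap and excluded from the ordering, not given an
arrangement class. Multi-finger proteins get an arrangement only when all
EARs lie strictly to one side of all fingers.

## Genome context

"Within 100 adjacent gene models" is read as a rank distance ≤ 100 between
*consecutive* family members, chained transitively — a cluster may
therefore span more than 100 ranks end to end. This matches the
convention of tandem-duplication callers and permits the 2–6-member
clusters the method is meant to find. Clusters are per-chromosome only.
Gene ranks are dense per chromosome, ordered by start (ties by id).

## pI and MW

MW is the sum of average residue masses plus one water (75.07 Da for
glycine as the unit check). pI bisects the net-charge curve on pH 0–14
until |charge| < 1e-4 or 100 iterations, using the published Bjellqvist
pKa table — the one behind the ExPASy Compute pI/Mw service — including
its residue-specific N-/C-terminal adjustments; the table name is recorded
in every result. Tests cross-check both quantities against Biopython's
independent implementation of the same table; note Biopython's `pi()`
brackets its search at [4.05, 12] and therefore clamps extremely acidic
sequences, where the unclamped bisection is the correct zero.

## Expression

Values are log2(x+1)-transformed; probesets collapse to genes by mean.
Tiers are tertiles (equal-count quantile splits) of mean log2 abundance,
ties broken by gene id, cut values reported — chosen because the
low/medium/high grouping this mirrors has no published thresholds.
"Obvious induction" is operationalized as target-tissue mean ≥ 2× the
non-target mean (configurable); the score denominator is floored at a
small epsilon so nodule-only genes get large finite scores, and the score
is scale-invariant.

## The synthetic generator

`medicago_like_spec(seed)` encodes the reference scenario as defaults: a
candidate proteome of 500 records — 216 regular family proteins + TRM1,
55 false candidates that fail confirmation, 12 truncated splice variants,
216 motif-free decoys — plus a separately returned nine-finger TFIIIA, so
confirmation arithmetic is 272 candidates → 217 confirmed → 218 with
TFIIIA appended, carrying 328 + 9 = 337 fingers. Planted composition:
Q 93 (Q1–Q6 = 28/22/12/10/10/11), QM 57 over nine cores, IDD 19, Z 41
over eight subgroups (2–15 members), C 127; finger counts
151/38/16/9/1/2/1 for 1/2/3/4/5/6/9 fingers; single-finger EAR layout
74 none / 59 downstream / 1 upstream / 9 between / 7 one-side / 1 triple;
tandem linkers as described for the array-bearing proteins (0/5/10 for
two-finger arrays, 10+10, 10+9+65, six-finger arrays, the TFIIIA
25/7,8/30/5–8 layout, and TRM1's 29/30/29/65 — which, at ≥ 11 residues,
correctly does *not* form an array under the operational rule, so 14
proteins carry arrays); 46 duplication clusters of sizes 6,5,4,4,3×4,2×38
across eight chromosomes with 59 family genes on chr1; 119
probeset-mapped genes in three abundance tiers 4 log2 units apart
(tier sd 0.4, tissue noise sd 0.2 — chosen so tier recovery is limited by
measurement noise, not construction) and 14 nodule-induced genes at folds
6–32. Q5 fingers are planted only with the `KRS` inter-His variant since
`KRC` would put a Cys in a wildcard region.

**Cleanliness guarantee.** Flanks, linkers and motif wildcard positions
are drawn from an alphabet excluding C, H and L; EAR wildcard slots
additionally exclude D and N (so a planted LxLxL cannot combine with
flanking residues into an accidental DLNxxP). Consequently the planted
fingers and EAR sites are provably the only pattern matches, and the
scanner's recovery on generated data is exactly 100% with zero false
positives — which is what the end-to-end tests assert. Every constructed
finger is additionally verified against the scanner and classifier before
acceptance (resampled up to 100 times, then an error).

What the generator does **not** emulate: realistic amino-acid
composition, homology between family members, sequencing/annotation
artifacts, or dirty sequence where decoys can contain C/H/L (a spec flag
allows such alphabets for stress-testing the overlap policies, at the
price of the exact-recovery guarantee). Passing tests therefore certify
the pipeline's bookkeeping and rule logic, not scan specificity on real
proteomes — that is what the external confirmation step is for.

## Numerical and determinism choices

All randomness flows from one integer seed through seeded NumPy
generators (sub-streams per stage). Sorts are stable with documented tie
breaks (gene id, protein id, feature start); rerunning any stage on the
same inputs is byte-identical. Internal protein coordinates are 0-based
half-open; exported feature files are 1-based inclusive (GFF convention).
Degenerate inputs: empty FASTA and duplicate headers are format errors;
motif-less proteins are simply not ZFPs; an empty annotation set yields
header-only outputs; `X` residues scan as wildcards, default to a 110 Da
stand-in mass in bulk MW tables, and are stripped for pI.

## Problem sizes

The packaged scenario scans 500 proteins (~170 k residues), lays out
~19 000 gene models and tiers 119 genes; the full pipeline runs in well
under a minute on one CPU, and the whole test suite in a few seconds.
Splice-variant handling defaults to longest-per-gene so family counts are
per gene; cross-annotation-version merging is left to an explicit id-pair
mapping supplied by the user rather than guessed.

## Known limitations

- The packaged IDD profile and Z core table are constructed surrogates;
  reproducing a real study's IDD/Z/QM subgroup counts exactly requires
  loading that study's reference tables through the config hooks.
- The EAR pattern set is the two canonical classes; studies using wider
  EAR definitions should extend `ear_patterns` in the rules file.
- Candidate bookkeeping counts proteins, so a confirmation list that
  drops k candidates always removes at least k motifs; published tallies
  that violate this arithmetic cannot be reproduced exactly by any
  protein-level filter.
- Multi-EAR arrangements beyond the two-EAR cases are reported as `mixed`
  with raw coordinates rather than given a finer taxonomy.
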